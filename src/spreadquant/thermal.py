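"""Thermal-potential-range normalization and fast/slow classification.

A species' spread in raw km²/yr conflates dispersal ability with thermal
opportunity: a cold-limited species can only ever occupy the warm part of
the region. The potential range corrects for this. The region is divided
into nested thermal zones by minimum January water temperature; the
potential range of a species with lower lethal temperature (LLT) t is the
total area of the zones whose minimum temperature is at or above t. The
zone table stores cumulative areas directly: one lookup per species.

The normalized statistic is

    percent range per year = (occupied area / potential range × 100) / years

classified fast at or above a cutoff (default 0.16 %/yr) and slow below.
Values are carried at full precision internally and rounded only at report
time — spread rate to the nearest integer, percent range per year to three
decimals, both half-away-from-zero — and classification is applied to the
rounded percentage by default so a reported table is self-consistent
(``classify_on_raw=True`` classifies on the unrounded value).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ThermalZoneTable",
    "SpeciesRecord",
    "DEFAULT_CUTOFF",
    "potential_range",
    "pct_range_per_year",
    "classify_spreader",
    "build_species_table",
    "load_florida_zones",
    "load_florida_species",
    "round_half_up",
]

DEFAULT_CUTOFF = 0.16

TABLE_COLUMNS = (
    "species",
    "years",
    "area_km2",
    "spread_rate",
    "llt_c",
    "potential_range_km2",
    "pct_range_per_yr",
    "category",
)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ThermalZoneTable:
    """Cumulative thermal-zone areas keyed by LLT upper bound.

    ``bounds_c`` are strictly ascending temperatures (°C); ``areas_km2``
    are strictly descending cumulative areas. ``areas_km2[i]`` is the
    total area with minimum water temperature at or above any LLT in
    ``(bounds_c[i-1], bounds_c[i]]``; the first area is the whole region.
    """

    bounds_c: tuple[float, ...]
    areas_km2: tuple[float, ...]

    def __post_init__(self):
        b = np.asarray(self.bounds_c, dtype=float)
        a = np.asarray(self.areas_km2, dtype=float)
        if b.size == 0 or b.size != a.size:
            raise ValueError("zone table needs equal, non-zero numbers of bounds and areas")
        if not np.all(np.diff(b) > 0):
            raise ValueError("zone bounds must be strictly ascending")
        if not np.all(np.diff(a) < 0):
            raise ValueError("zone areas must be strictly descending")

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "ThermalZoneTable":
        df = pd.read_csv(path)
        return cls(
            bounds_c=tuple(df["llt_upper_bound_c"].astype(float)),
            areas_km2=tuple(df["potential_area_km2"].astype(float)),
        )

    def potential_range(self, llt_c: float) -> float:
        """Area (km²) thermally available to a species with the given LLT.

        The first zone whose bound is at or above the LLT applies: a
        species occupies every zone no colder than its lower lethal
        temperature (inclusive at the bound).
        """
        for bound, area in zip(self.bounds_c, self.areas_km2):
            if llt_c <= bound:
                return float(area)
        raise ValueError(
            f"LLT {llt_c} °C exceeds the warmest zone bound "
            f"({self.bounds_c[-1]} °C): no potential range in the region"
        )


@dataclass(frozen=True)
class SpeciesRecord:
    """Inputs needed to classify one species' spread."""

    species_id: str
    years: int
    llt_c: float
    occupied_area_km2: float


def load_florida_zones() -> ThermalZoneTable:
    """Packaged peninsular-Florida thermal zone table (January minima)."""
    with resources.as_file(
        resources.files("spreadquant.data") / "thermal_zones_florida.csv"
    ) as p:
        return ThermalZoneTable.from_csv(p)


def load_florida_species() -> list[SpeciesRecord]:
    """Packaged table of 31 established non-native Florida fishes.

    Columns: years since first collection record, occupied area (km²),
    and lower lethal temperature (°C).
    """
    with resources.as_file(
        resources.files("spreadquant.data") / "table1_florida.csv"
    ) as p:
        df = pd.read_csv(p)
    return [
        SpeciesRecord(
            species_id=row.species,
            years=int(row.years),
            llt_c=float(row.llt_c),
            occupied_area_km2=float(row.area_km2),
        )
        for row in df.itertuples(index=False)
    ]


def potential_range(llt_c: float, zones: ThermalZoneTable) -> float:
    """Functional form of :meth:`ThermalZoneTable.potential_range`."""
    return zones.potential_range(llt_c)


def pct_range_per_year(
    occupied_area_km2: float, potential_range_km2: float, years: int
) -> float:
    """Percent of the potential range colonized per year since first record."""
    if potential_range_km2 <= 0:
        raise ValueError("potential range must be positive")
    if years < 1:
        raise ValueError("years must be >= 1")
    return (occupied_area_km2 / potential_range_km2 * 100.0) / years


def classify_spreader(pct: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """'fast' at or above the cutoff, 'slow' below."""
    if pct < 0:
        raise ValueError("percent range per year cannot be negative")
    return "fast" if pct >= cutoff else "slow"


def build_species_table(
    records: Iterable[SpeciesRecord],
    zones: ThermalZoneTable,
    cutoff: float = DEFAULT_CUTOFF,
    classify_on_raw: bool = False,
) -> pd.DataFrame:
    """Assemble the per-species spread classification table.

    One row per species with spread rate (nearest integer), potential
    range, percent range per year (3 d.p.) and fast/slow category, plus
    unrounded ``spread_rate_raw`` / ``pct_raw`` columns for downstream
    computation. Per-row failures are re-raised with the species id.
    """
    rows = []
    for rec in records:
        try:
            pot = zones.potential_range(rec.llt_c)
            rate_raw = rec.occupied_area_km2 / rec.years if rec.years >= 1 else None
            if rate_raw is None:
                raise ValueError(f"years must be >= 1, got {rec.years}")
            pct_raw = pct_range_per_year(rec.occupied_area_km2, pot, rec.years)
        except ValueError as exc:
            raise ValueError(f"{rec.species_id}: {exc}") from exc
        pct_rounded = round_half_up(pct_raw, 3)
        category = classify_spreader(pct_raw if classify_on_raw else pct_rounded, cutoff)
        rows.append(
            {
                "species": rec.species_id,
                "years": rec.years,
                "area_km2": rec.occupied_area_km2,
                "spread_rate": int(round_half_up(rate_raw, 0)),
                "llt_c": rec.llt_c,
                "potential_range_km2": pot,
                "pct_range_per_yr": pct_rounded,
                "category": category,
                "spread_rate_raw": rate_raw,
                "pct_raw": pct_raw,
            }
        )
    columns = list(TABLE_COLUMNS) + ["spread_rate_raw", "pct_raw"]
    return pd.DataFrame(rows, columns=columns)
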