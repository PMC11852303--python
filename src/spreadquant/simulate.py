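"""Seed-deterministic synthetic data with planted ground truth.

Two generators stand in for the external inputs of the analysis:

* ``simulate_occurrences`` emulates a NAS-style occurrence extract —
  per-species clouds of points drawn from isotropic bivariate normals
  (dispersion given in km, converted to degrees locally) around planted
  cluster centers, plus uniform noise points in a bounding box. The
  planted memberships and realized hull areas are returned alongside the
  records so recovery can be checked exactly.

* ``simulate_traits`` emulates a life-history trait table on the 15-trait
  schema — truncated normals for continuous traits (bounded to each
  trait's documented range, targeting its documented mean and SD),
  integer-uniform draws over the range for ordinal traits, Bernoulli
  draws at the documented mean for binary traits. Fast/slow labels are
  Bernoulli with a logistic link on chosen standardized traits, and the
  true effect vector is returned.

Every generator takes a seed and is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .occurrences import OccurrenceRecord, OccurrenceSet, Status
from .spread import minimum_convex_polygon
from .traits import TRAITS, TraitDef

__all__ = [
    "ClusterSpec",
    "SpeciesOccSpec",
    "OccurrenceSimSpec",
    "OccurrenceTruth",
    "TraitSimSpec",
    "simulate_occurrences",
    "simulate_traits",
]

_KM_PER_DEG = 111.19492664455873  # 2πR/360 at R = 6371.0088 km


@dataclass(frozen=True)
class ClusterSpec:
    """One planted occurrence cluster."""

    center_lon: float
    center_lat: float
    dispersion_km: float
    n_points: int

    def __post_init__(self):
        if self.dispersion_km <= 0:
            raise ValueError("dispersion_km must be positive")
        if self.n_points < 0:
            raise ValueError("n_points must be >= 0")


@dataclass(frozen=True)
class SpeciesOccSpec:
    species_id: str
    clusters: tuple[ClusterSpec, ...]
    n_noise: int = 0
    first_year: int = 2000


@dataclass(frozen=True)
class OccurrenceSimSpec:
    """Full specification of one synthetic occurrence extract.

    Noise points are uniform in ``noise_box`` (lon_min, lon_max, lat_min,
    lat_max) and carry non-established status with probability
    ``noise_other_frac``; planted cluster points are always established
    so the planted truth survives the status filter.
    """

    species: tuple[SpeciesOccSpec, ...]
    noise_box: tuple[float, float, float, float] = (-88.0, -79.0, 24.0, 31.0)
    noise_other_frac: float = 0.0
    reference_year: int = 2024

    def __post_init__(self):
        lon0, lon1, lat0, lat1 = self.noise_box
        if not (lon0 < lon1 and lat0 < lat1):
            raise ValueError("invalid noise bounding box")
        if not 0.0 <= self.noise_other_frac <= 1.0:
            raise ValueError("noise_other_frac must be in [0, 1]")


@dataclass
class OccurrenceTruth:
    """Planted ground truth emitted with a synthetic occurrence set."""

    # species_id -> list of per-cluster record-index lists (into the set)
    memberships: dict[str, list[list[int]]] = field(default_factory=dict)
    # species_id -> list of realized planted-cluster hull areas (km²)
    hull_areas_km2: dict[str, list[float]] = field(default_factory=dict)


def simulate_occurrences(
    spec: OccurrenceSimSpec, seed: int
) -> tuple[OccurrenceSet, OccurrenceTruth]:
    """Draw a synthetic occurrence set with its planted truth."""
    rng = np.random.default_rng(seed)
    records: list[OccurrenceRecord] = []
    truth = OccurrenceTruth()
    for sp in spec.species:
        truth.memberships[sp.species_id] = []
        truth.hull_areas_km2[sp.species_id] = []
        for cl in sp.clusters:
            offsets_km = rng.normal(0.0, cl.dispersion_km, size=(cl.n_points, 2))
            lat = cl.center_lat + offsets_km[:, 1] / _KM_PER_DEG
            lon = cl.center_lon + offsets_km[:, 0] / (
                _KM_PER_DEG * np.cos(np.radians(cl.center_lat))
            )
            years = rng.integers(sp.first_year, spec.reference_year + 1, cl.n_points)
            idx = []
            pts = []
            for x, y, yr in zip(lon, lat, years):
                idx.append(len(records))
                pts.append((float(x), float(y)))
                records.append(
                    OccurrenceRecord(
                        sp.species_id, float(x), float(y), int(yr), Status.ESTABLISHED
                    )
                )
            truth.memberships[sp.species_id].append(idx)
            if len(pts) >= 3:
                truth.hull_areas_km2[sp.species_id].append(
                    minimum_convex_polygon(pts).area_km2
                )
            else:
                truth.hull_areas_km2[sp.species_id].append(0.0)
        lon0, lon1, lat0, lat1 = spec.noise_box
        for _ in range(sp.n_noise):
            status = (
                Status.OTHER
                if rng.random() < spec.noise_other_frac
                else Status.ESTABLISHED
            )
            records.append(
                OccurrenceRecord(
                    sp.species_id,
                    float(rng.uniform(lon0, lon1)),
                    float(rng.uniform(lat0, lat1)),
                    int(rng.integers(sp.first_year, spec.reference_year + 1)),
                    status,
                )
            )
    return OccurrenceSet.from_records(records), truth


@dataclass(frozen=True)
class TraitSimSpec:
    """Specification of a synthetic trait table with a logistic label link.

    ``beta`` maps trait names to effects on the log-odds of being a fast
    spreader, applied to per-sample z-scored trait columns; ``intercept``
    shifts the overall fast fraction (0 → about half fast).
    """

    n_species: int
    beta: Mapping[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    traits: tuple[TraitDef, ...] = TRAITS

    def __post_init__(self):
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        known = {t.name for t in self.traits}
        unknown = set(self.beta) - known
        if unknown:
            raise ValueError(f"beta refers to unknown traits: {sorted(unknown)}")


def _draw_trait(t: TraitDef, n: int, rng: np.random.Generator) -> np.ndarray:
    if t.kind == "continuous":
        a = (t.lo - t.mean) / t.sd
        b = (t.hi - t.mean) / t.sd
        return scipy.stats.truncnorm.rvs(
            a, b, loc=t.mean, scale=t.sd, size=n, random_state=rng
        )
    if t.kind == "ordinal":
        return rng.integers(int(t.lo), int(t.hi) + 1, size=n).astype(float)
    if t.kind == "binary":
        return (rng.random(n) < t.mean).astype(float)
    raise ValueError(f"unknown trait kind: {t.kind!r}")


def simulate_traits(
    spec: TraitSimSpec, seed: int
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Draw a synthetic trait table, fast/slow labels, and the truth.

    Returns ``(traits_df, labels, truth)`` where ``labels`` is a 0/1
    Series (1 = fast) and ``truth`` records the effect vector and the
    standardization used in the link.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_species
    index = pd.Index([f"sp{i + 1:04d}" for i in range(n)], name="species")
    cols = {t.name: _draw_trait(t, n, rng) for t in spec.traits}
    df = pd.DataFrame(cols, index=index)

    eta = np.full(n, spec.intercept, dtype=float)
    standardization = {}
    for name, b in spec.beta.items():
        col = df[name].to_numpy()
        mu, sd = float(col.mean()), float(col.std(ddof=0))
        sd = sd if sd > 0 else 1.0
        standardization[name] = (mu, sd)
        eta += b * (col - mu) / sd
    p = 1.0 / (1.0 + np.exp(-eta))
    labels = pd.Series((rng.random(n) < p).astype(int), index=index, name="fast")
    truth = {
        "beta": dict(spec.beta),
        "intercept": spec.intercept,
        "standardization": standardization,
        "p_fast": p,
    }
    return df, labels, truth
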