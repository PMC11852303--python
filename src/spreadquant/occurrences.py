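"""Reading, validating, and filtering point occurrence records.

Input is a delimited export in the style of the USGS Nonindigenous Aquatic
Species (NAS) database: one row per collection record with a species name,
WGS84 decimal-degree coordinates, a record year, and a population status.
Rows that fail validation are counted and reported, never silently dropped.
Only records whose status is "established" (a self-sustaining population)
enter the spread analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Mapping, Union

import pandas as pd

__all__ = [
    "Status",
    "OccurrenceRecord",
    "OccurrenceSet",
    "ReadReport",
    "ColumnMapError",
    "DEFAULT_COLUMN_MAP",
    "DEFAULT_REFERENCE_YEAR",
    "read_occurrences",
    "write_occurrences",
    "filter_established",
]

#: Default NAS-style column names; override via ``column_map``.
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "species": "scientificName",
    "lon": "longitude",
    "lat": "latitude",
    "year": "year",
    "status": "status",
}

#: Latest record year accepted by default (NAS snapshot vintage).
DEFAULT_REFERENCE_YEAR = 2025

#: Normalized column order used for all downstream CSV artifacts.
CANONICAL_COLUMNS = ("species_id", "lon", "lat", "year", "status")


class ColumnMapError(KeyError):
    """A mapped column is missing from the input header."""


class Status(str, Enum):
    ESTABLISHED = "established"
    OTHER = "other"

    @classmethod
    def parse(cls, raw: object) -> "Status":
        # Case-insensitive match on the exact token "established";
        # everything else (incl. blank) maps to OTHER.
        if str(raw).strip().lower() == "established":
            return cls.ESTABLISHED
        return cls.OTHER


@dataclass(frozen=True)
class OccurrenceRecord:
    species_id: str
    lon: float
    lat: float
    year: int
    status: Status


@dataclass
class ReadReport:
    """Accounting of a read: every input row is either kept or explained."""

    n_rows: int = 0
    n_valid: int = 0
    n_rejected: int = 0
    n_deduplicated: int = 0
    rejections: list = field(default_factory=list)  # (row_number, reason)


class OccurrenceSet:
    """Ordered collection of occurrence records with per-species retrieval.

    Backed by a DataFrame in canonical column order; row order is the
    order of ingestion.
    """

    def __init__(self, frame: pd.DataFrame, report: ReadReport | None = None):
        missing = set(CANONICAL_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"occurrence frame missing columns: {sorted(missing)}")
        self._frame = frame.loc[:, list(CANONICAL_COLUMNS)].reset_index(drop=True)
        self.report = report if report is not None else ReadReport(
            n_rows=len(frame), n_valid=len(frame)
        )

    # -- construction -------------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[OccurrenceRecord]) -> "OccurrenceSet":
        rows = [
            (r.species_id, r.lon, r.lat, r.year, r.status.value) for r in records
        ]
        frame = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
        if frame.empty:
            frame = _empty_frame()
        return cls(frame)

    # -- container protocol --------------------------------------------------

    def __len__(self) -> int:
        return len(self._frame)

    def __iter__(self):
        for row in self._frame.itertuples(index=False):
            yield OccurrenceRecord(
                row.species_id, row.lon, row.lat, int(row.year), Status(row.status)
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, OccurrenceSet):
            return NotImplemented
        return self._frame.equals(other._frame)

    @property
    def frame(self) -> pd.DataFrame:
        """Canonical-order DataFrame view (copy) of the records."""
        return self._frame.copy()

    @property
    def species(self) -> list[str]:
        """Distinct species ids in first-appearance order."""
        return list(dict.fromkeys(self._frame["species_id"]))

    def for_species(self, species_id: str) -> pd.DataFrame:
        """All records of one species, ingestion order preserved."""
        return self._frame[self._frame["species_id"] == species_id].copy()

    def first_record_year(self, species_id: str) -> int:
        sub = self.for_species(species_id)
        if sub.empty:
            raise KeyError(f"unknown species: {species_id!r}")
        return int(sub["year"].min())


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species_id": pd.Series(dtype=str),
            "lon": pd.Series(dtype=float),
            "lat": pd.Series(dtype=float),
            "year": pd.Series(dtype=int),
            "status": pd.Series(dtype=str),
        }
    )


def _validate_row(
    row: Mapping[str, object], colmap: Mapping[str, str], reference_year: int
):
    """Return (record, None) for a well-formed row, (None, reason) otherwise."""
    species = str(row[colmap["species"]]).strip()
    species = " ".join(species.split())
    if not species or species.lower() in ("nan", "none"):
        return None, "empty species name"
    try:
        lon = float(row[colmap["lon"]])
        lat = float(row[colmap["lat"]])
    except (TypeError, ValueError):
        return None, "non-numeric coordinates"
    if not (-180.0 <= lon <= 180.0) or lon != lon:
        return None, f"longitude out of bounds: {lon}"
    if not (-90.0 <= lat <= 90.0) or lat != lat:
        return None, f"latitude out of bounds: {lat}"
    try:
        year = int(float(row[colmap["year"]]))
    except (TypeError, ValueError):
        return None, "non-numeric year"
    if not (1800 < year <= reference_year):
        return None, f"year out of range: {year}"
    status = Status.parse(row[colmap["status"]])
    return OccurrenceRecord(species, lon, lat, year, status), None


def read_occurrences(
    source: Union[str, Path, IO[str]],
    column_map: Mapping[str, str] | None = None,
    *,
    reference_year: int = DEFAULT_REFERENCE_YEAR,
    dedupe: bool = True,
) -> OccurrenceSet:
    """Read a NAS-style delimited occurrence file.

    Parameters
    ----------
    source
        Path or text stream of a CSV with a header row.
    column_map
        Maps the logical fields ``species, lon, lat, year, status`` to the
        file's column names; defaults to :data:`DEFAULT_COLUMN_MAP`.
    reference_year
        Records dated after this year are rejected.
    dedupe
        Collapse exact duplicates on (species, lon, lat, year). Repeated
        survey entries at one site should not pad a cluster to the
        three-point minimum.

    Returns
    -------
    OccurrenceSet
        With a :class:`ReadReport` on ``.report`` accounting for every row.
    """
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)

    raw = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise ColumnMapError(
            f"mapped column(s) not in header: {missing}; header={list(raw.columns)}"
        )

    report = ReadReport(n_rows=len(raw))
    records: list[OccurrenceRecord] = []
    for i, row in enumerate(raw.to_dict(orient="records")):
        rec, reason = _validate_row(row, colmap, reference_year)
        if rec is None:
            report.n_rejected += 1
            report.rejections.append((i + 2, reason))  # 1-based incl. header
        else:
            records.append(rec)
    report.n_valid = len(records)

    if dedupe and records:
        seen: set[tuple] = set()
        kept = []
        for rec in records:
            key = (rec.species_id, rec.lon, rec.lat, rec.year)
            if key in seen:
                report.n_deduplicated += 1
            else:
                seen.add(key)
                kept.append(rec)
        records = kept

    if report.n_valid == 0:
        warnings.warn("no valid occurrence rows in input", stacklevel=2)

    occ = OccurrenceSet.from_records(records)
    occ.report = report
    return occ


def write_occurrences(occ: OccurrenceSet, path: Union[str, Path, IO[str]]) -> None:
    """Write the normalized CSV (fixed canonical column order)."""
    occ.frame.to_csv(path, index=False)


def filter_established(occ: OccurrenceSet) -> OccurrenceSet:
    """Keep exactly the records with established status, order preserved."""
    frame = occ.frame
    kept = frame[frame["status"] == Status.ESTABLISHED.value]
    if kept.empty:
        kept = _empty_frame()
    return OccurrenceSet(kept.reset_index(drop=True))
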