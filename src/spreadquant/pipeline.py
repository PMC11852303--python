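"""End-to-end orchestration of the spread and trait analyses.

Two entry modes mirror how the analysis is reproduced in practice:

* **precomputed mode** — a species table with years since first record,
  occupied area, and lower lethal temperature is classified directly
  (the packaged 31-species Florida table reproduces the published
  derived columns this way);
* **occurrence mode** — the full chain from raw occurrence records:
  validate → keep established → cluster → hulls → areas → years from the
  first record → normalize by potential range → classify.

Row-level problems (e.g., a species with no lower-lethal-temperature
entry) are reported and skipped; the run continues.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import spread, thermal
from .occurrences import filter_established, read_occurrences
from .traits import (
    DEFAULT_CDA_EXCLUDED,
    canonical_discriminant,
    fit_logistic,
    full_factorial,
    main_effects,
    model_comparison_table,
    stepwise_aic,
    u_test_table,
    validate_trait_table,
)

__all__ = ["RunConfig", "run_spread_pipeline", "run_trait_pipeline"]

log = logging.getLogger("spreadquant")

#: The three reference model formulas reported alongside the stepwise
#: winner: the full-factorial and additive models on the three focal
#: traits, and the additive model suggested by the per-trait tests.
REPORTED_MODEL_SPECS = (
    full_factorial("max_length", "diet_breadth", "length_at_maturation"),
    main_effects("max_length", "diet_breadth", "length_at_maturation"),
    main_effects(
        "max_length",
        "length_at_maturation",
        "fecundity",
        "parental_care",
        "salinity_tolerance",
    ),
)


@dataclass
class RunConfig:
    """Configuration of a spread-quantification run."""

    occurrences: str | Path | None = None
    species_table: str | Path | None = None
    llt_table: str | Path | None = None
    zones: str | Path | None = None
    link_km: float = spread.DEFAULT_LINK_KM
    min_size: int = spread.DEFAULT_MIN_SIZE
    cutoff: float = thermal.DEFAULT_CUTOFF
    classify_on_raw: bool = False
    reference_year: int = 2024
    excluded_traits: tuple[str, ...] = DEFAULT_CDA_EXCLUDED
    seed: int = 0
    out_dir: str | Path | None = None

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.occurrences is None and self.species_table is None:
            raise ValueError("provide occurrences or a precomputed species table")
        for p in (self.occurrences, self.species_table, self.llt_table, self.zones):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def load_zones(self) -> thermal.ThermalZoneTable:
        if self.zones is None:
            return thermal.load_florida_zones()
        return thermal.ThermalZoneTable.from_csv(self.zones)


def _polygons_geojson(results: Sequence[spread.SpreadResult]) -> dict:
    features = []
    for res in results:
        for i, poly in enumerate(res.polygons):
            features.append(
                {
                    "type": "Feature",
                    "geometry": poly.shapely.__geo_interface__,
                    "properties": {
                        "species": res.species_id,
                        "cluster": i,
                        "n_points": len(res.clusters[i]),
                        "area_km2": poly.area_km2,
                        "degenerate": poly.degenerate,
                    },
                }
            )
    return {"type": "FeatureCollection", "features": features}


def run_spread_pipeline(config: RunConfig):
    """Run the spread analysis; returns ``(table, artifacts)``.

    ``table`` is the per-species classification DataFrame; ``artifacts``
    carries the quantification detail, row-level errors, and paths of any
    files written under ``config.out_dir``.
    """
    zones = config.load_zones()
    artifacts: dict = {"row_errors": [], "written": []}

    if config.species_table is not None:
        df = pd.read_csv(config.species_table)
        records = [
            thermal.SpeciesRecord(
                species_id=str(r.species),
                years=int(r.years),
                llt_c=float(r.llt_c),
                occupied_area_km2=float(r.area_km2),
            )
            for r in df.itertuples(index=False)
        ]
        log.info("precomputed mode: %d species", len(records))
    else:
        occ = read_occurrences(config.occurrences, reference_year=config.reference_year)
        log.info(
            "read %d rows: %d valid, %d rejected, %d duplicates collapsed",
            occ.report.n_rows,
            occ.report.n_valid,
            occ.report.n_rejected,
            occ.report.n_deduplicated,
        )
        for row, reason in occ.report.rejections:
            artifacts["row_errors"].append(("input", f"row {row}: {reason}"))
        est = filter_established(occ)
        log.info("established filter: %d -> %d records", len(occ), len(est))
        if len(est) == 0:
            log.warning("no established records; empty result")

        llt_map: dict[str, float] = {}
        if config.llt_table is not None:
            llt_df = pd.read_csv(config.llt_table)
            llt_map = dict(
                zip(llt_df["species"].astype(str), llt_df["llt_c"].astype(float))
            )

        results = []
        records = []
        for sp in est.species:
            res = spread.occupied_area(
                est, sp, link_km=config.link_km, min_size=config.min_size
            )
            years = config.reference_year - est.first_record_year(sp)
            years = max(years, 1)  # first seen this year: one year of spread
            res.years_since_first_record = years
            res.spread_rate_km2_per_yr = spread.spread_rate(
                res.occupied_area_km2, years
            )
            results.append(res)
            if sp not in llt_map:
                artifacts["row_errors"].append(
                    (sp, "no lower lethal temperature entry; not classified")
                )
                continue
            records.append(
                thermal.SpeciesRecord(
                    species_id=sp,
                    years=years,
                    llt_c=llt_map[sp],
                    occupied_area_km2=res.occupied_area_km2,
                )
            )
        artifacts["spread_results"] = results
        artifacts["quantification"] = pd.DataFrame(
            [
                {
                    "species": r.species_id,
                    "n_points": r.n_points,
                    "n_clusters": len(r.clusters),
                    "occupied_area_km2": r.occupied_area_km2,
                    "years": r.years_since_first_record,
                    "spread_rate": r.spread_rate_km2_per_yr,
                }
                for r in results
            ]
        )

    table = thermal.build_species_table(
        records, zones, cutoff=config.cutoff, classify_on_raw=config.classify_on_raw
    )
    n_fast = int((table["category"] == "fast").sum())
    log.info("classified %d species: %d fast, %d slow", len(table), n_fast, len(table) - n_fast)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table_path = out / "species_classification.csv"
        table.loc[:, list(thermal.TABLE_COLUMNS)].to_csv(table_path, index=False)
        artifacts["written"].append(table_path)
        if "quantification" in artifacts:
            qpath = out / "spread_quantification.csv"
            artifacts["quantification"].to_csv(qpath, index=False)
            artifacts["written"].append(qpath)
            gpath = out / "range_polygons.geojson"
            gpath.write_text(json.dumps(_polygons_geojson(artifacts["spread_results"])))
            artifacts["written"].append(gpath)
    return table, artifacts


def run_trait_pipeline(
    traits_df: pd.DataFrame,
    labels,
    excluded_traits: Sequence[str] = DEFAULT_CDA_EXCLUDED,
    candidates: Sequence[str] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the trait battery; returns a dict of result tables.

    ``labels`` is 0/1 (1 = fast), aligned with ``traits_df``. Requires at
    least four species per group. Emits the per-trait U-test table, the
    AIC model-comparison table (stepwise winner plus the reference
    formulas), and the CDA scores/structure.
    """
    clean, excluded = validate_trait_table(traits_df)
    labels = pd.Series(labels).loc[clean.index]
    y = labels.to_numpy().astype(int)
    if (y == 1).sum() < 4 or (y == 0).sum() < 4:
        raise ValueError(
            f"need >= 4 species per group, got {int((y == 1).sum())} fast / "
            f"{int((y == 0).sum())} slow"
        )
    if excluded:
        log.warning("excluded %d species with missing traits: %s", len(excluded), excluded)

    u_table = u_test_table(clean, y)

    best = stepwise_aic(y, clean, candidates=candidates)
    models = [best] + [
        fit_logistic(y, clean, spec)
        for spec in REPORTED_MODEL_SPECS
        if tuple(spec) != best.terms
    ]
    model_table = model_comparison_table(models)

    cda = canonical_discriminant(clean, y, exclude=excluded_traits)
    cda_scores = pd.DataFrame(
        {"canonical_score": cda.scores, "fast": y}, index=clean.index
    )

    out_tables = {
        "u_tests": u_table,
        "models": model_table,
        "stepwise": best,
        "cda": cda,
        "cda_scores": cda_scores,
        "cda_structure": cda.structure.rename_axis("trait").reset_index(),
        "excluded_species": excluded,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        u_table.to_csv(out / "u_tests.csv", index=False)
        model_table.to_csv(out / "model_comparison.csv", index=False)
        cda_scores.to_csv(out / "cda_scores.csv")
        out_tables["cda_structure"].to_csv(out / "cda_structure.csv", index=False)
    return out_tables
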