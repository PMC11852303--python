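# spreadquant

Quantify and predict the geographic spread of established non-native
freshwater fishes from point occurrence records and life-history traits.

In regions like peninsular Florida — flat, hydrologically interconnected,
with thousands of water bodies — classic spread measures (counts of occupied
watersheds, lakes, or river kilometers) break down. `spreadquant` implements
an area-based alternative aimed at invasion ecologists and risk assessors:

1. **Spread quantification.** For each species, occurrence records with
   *established* status are grouped by single-linkage connectivity: two
   records are neighbors if their great-circle distance is ≤ 50 km, and
   connected components with fewer than 3 points are discarded (any point
   more than 50 km from its closest neighbor can never join a cluster).
   Each cluster's minimum convex polygon (MCP) is built and its area
   measured in an equal-area projection. The occupied area *A* (sum of MCP
   areas, km²) over the years *t* since the species' first record gives the
   spread rate *A/t* in km²/yr.
2. **Thermal normalization.** Raw km²/yr penalizes cold-limited species that
   could never occupy the whole region. Each species' potential range *P* is
   the total area of the thermal zones whose minimum January water
   temperature is at or above its lower lethal temperature (LLT). The
   normalized statistic is the percent of potential range colonized per
   year, (*A*/*P* × 100)/*t*, classified **fast** at or above a cutoff of
   0.16 %/yr and **slow** below.
3. **Trait prediction.** Given a table of 15 life-history traits per species
   (body size, diet breadth, fecundity, parental care, salinity tolerance,
   …), the package runs per-trait two-sided Mann–Whitney U tests,
   logistic regression with bi-directional stepwise AIC selection, and
   two-group canonical discriminant analysis (structure coefficients =
   trait–axis correlations) to separate fast from slow spreaders.

A seed-deterministic synthetic-data generator produces occurrence extracts
with planted clusters and trait tables with a known logistic trait→label
link, so every stage is testable without external downloads.

## Worked example

```python
import spreadquant as sq

records = sq.load_florida_species()   # 31 species: years, area (km²), LLT (°C)
zones = sq.load_florida_zones()       # thermal zones: LLT bound -> area (km²)
table = sq.build_species_table(records, zones, cutoff=0.16)
print(table["category"].value_counts().to_dict())
```

prints `{'slow': 18, 'fast': 13}`: of the 31 established species, 18 are
slow spreaders and 13 fast. The fastest normalized spreader is the brown
hoplo *Hoplosternum littorale* (spread rate 2769 km²/yr; 2.157 % of its
128,371 km² potential range per year), while the croaking gourami
*Trichopsis vittata* has spread at an unmeasurable 0.000 %/yr. The butterfly
peacock bass *Cichla ocellaris* shows why normalization matters: a modest
321 km²/yr over a cold-limited 32,026 km² potential range is still
1.001 %/yr — a fast spreader within the range it can occupy.

The `examples/` directory holds one short narrative script per capability:

- `examples/classify_florida_species.py` — the classification above, with
  the five fastest and slowest species;
- `examples/quantify_synthetic_spread.py` — full chain from raw occurrence
  points (clustering → MCPs → equal-area km²) on a planted two-cluster
  extract, recovered area vs planted truth;
- `examples/trait_battery.py` — U tests, stepwise-AIC model selection, and
  CDA on a synthetic trait table with a planted maximum-length effect.

A thin CLI mirrors the stages:

```bash
spreadquant classify --species-table species.csv --cutoff 0.16
spreadquant quantify --occurrences nas_export.csv --link-km 50 --min-size 3
spreadquant traits --trait-table traits.csv --classes classes.csv
spreadquant simulate occurrences --spec spec.yaml --seed 7 --out sim/
```

## Layout

- `src/spreadquant/occurrences.py` — NAS-style CSV ingestion, validation,
  established-status filter
- `src/spreadquant/spread.py` — haversine distances, single-linkage
  clustering, MCPs, occupied area, spread rate
- `src/spreadquant/projection.py` — spherical Albers equal-area projection
- `src/spreadquant/thermal.py` — zone table, potential range, %-range/yr,
  fast/slow classification
- `src/spreadquant/traits.py` — U tests, logistic + stepwise AIC, CDA
- `src/spreadquant/simulate.py` — synthetic occurrences and trait tables
  with planted truth
- `src/spreadquant/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
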