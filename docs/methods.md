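# Methods

This note documents the models and procedures implemented in
`spreadquant`, the parameters that matter, the numerical choices, and what
the synthetic-data tests do and do not establish about real data.

## Spread quantification

**Clustering rule.** Per species, retained (established-status) occurrence
points are clustered by single-linkage connectivity: an edge joins any two
points whose great-circle distance is at most `link_km` (default **50 km**),
and connected components with fewer than `min_size` points (default **3**)
are discarded. This is the graph-theoretic reading of "exclude any point
more than 50 km from its closest neighbor, keep clusters of at least three
points": a point > 50 km from its nearest neighbor is isolated in the graph
and can never reach the size threshold. It is equivalent to DBSCAN with
eps = 50 km, minPts = 1, followed by a component-size filter. Single linkage
chains: points 40 km + 40 km apart along a line form one cluster even though
the endpoints are 80 km apart. The rule needs no iteration — connected
components are a fixed point of "drop points with no neighbor in the
cluster" — and has no tie-breaking sensitivity. Exact duplicate records
(same species, lon, lat, year) are collapsed on ingest by default
(`dedupe=True`) so repeated survey entries at one site cannot fabricate a
three-point cluster.

**Distances and areas.** The 50-km rule uses the haversine great-circle
distance on a sphere of radius 6371.0088 km (IUGG mean radius). Polygon
areas are computed by projecting hull vertices into a spherical Albers
equal-area conic projection parameterized per species from the point extent
(standard parallels at one-sixth insets of the latitude range — the usual
cartographic rule of thumb) and applying the planar shoelace formula; when
the standard parallels straddle the equator the projection degenerates to
its analytic limit, the Lambert cylindrical equal-area projection. The
projection is written in-package (a dozen closed-form lines) and validated
against the spherical closed form for a 1°×1° equatorial cell
(R²·Δλ·Δsin φ ≈ 12,364 km², agreement within 0.5%). For a species, all
cluster polygons share one projection so areas add in a single plane.
Residual error relative to true geodesic polygon area comes only from edge
straightness and is far below the tolerances used anywhere in the package.

**Degenerate hulls.** A cluster whose points are collinear has a zero-width
hull: it is kept in the output with `area_km2 = 0` and flagged `degenerate`
rather than dropped, so cluster counts remain faithful to the clustering
rule.

**Years since first record.** In occurrence mode, years = reference year −
earliest record year over *all* of the species' retained records, not just
clustered ones (clipped below at 1). In precomputed mode the years column is
consumed as given.

## Thermal potential range and classification

The region is partitioned into nested thermal zones by minimum January
water temperature. The packaged peninsular-Florida table stores cumulative
areas keyed by LLT upper bound:

| LLT bound (°C) | potential area (km²) |
|---|---|
| 8.6 | 141,300 |
| 11.0 | 128,371 |
| 12.5 | 111,523 |
| 13.5 | 75,038 |
| 15.0 | 32,026 |

A species' potential range is the area of the first zone whose bound is at
or above its LLT (inclusive: a species with LLT exactly equal to a zone's
minimum temperature survives there — required for the warmest-tolerance
species, LLT 15 °C, to have a nonzero range). The five areas and the 8.6 °C
coldest bound are fixed by the source map; the three interior bounds (11.0,
12.5, 13.5 °C) are defaults chosen inside the intervals that the packaged
31-species mapping constrains them to — the table is a two-column CSV
config, not code, and other regions substitute their own.

**Classification.** Percent range per year = (occupied area / potential
range × 100) / years, fast at or above `cutoff` (default **0.16 %/yr**,
inclusive), slow below. Values are carried at full precision internally and
rounded only at report time: spread rate to the nearest integer, percent to
three decimals, both half-away-from-zero (the convention of printed tables;
banker's rounding would disagree on exact .5 values such as a rate of
320.5). By default the category is assigned from the rounded percentage so
a reported table is self-consistent row by row; `classify_on_raw=True`
classifies on the unrounded value. The two conventions can only disagree
within ±0.0005 of the cutoff.

## Trait statistics

**Mann–Whitney U.** Per trait, the two-sided test comparing fast vs slow
groups. U is the rank-sum statistic with midranks for ties, reported for
the fast group (config-exposed; U_fast + U_slow = n₁n₂). The exact
permutation null is used when the combined sample is ≤ 12 with no ties;
otherwise the normal approximation with tie correction and continuity
correction (the two agree within 0.02 at n₁ = n₂ = 6). Computation is
delegated to `scipy.stats.mannwhitneyu`; the test suite checks it against
an independent brute-force enumeration of all group assignments. No
multiple-testing correction is applied across the 15 traits — raw p-values
are reported.

**Logistic regression.** Binomial-logit maximum likelihood via statsmodels
(Newton; IRLS fallback on a singular Hessian). Terms are trait names or
interaction tuples whose design columns are raw products; ordinal traits
(reproductive guild, salinity tolerance, …) enter as their numeric codes,
not dummy-expanded, matching how the schema documents them on numeric
scales. AIC = 2k − 2·logL by definition. With ~31 species, interaction
models frequently separate the groups completely; separation is detected
(|linear predictor| > 30 pins fitted probabilities at 0/1) and flagged, and
the log-likelihood is recomputed from clipped fitted probabilities so the
supremum logL → 0 yields a finite AIC → 2k instead of NaN. Separated models
are reported with their flag, never suppressed. Rank-deficient designs are
flagged likewise.

**Stepwise AIC.** Greedy bi-directional search from the intercept-only
model (the start point is an argument): each step evaluates every
single-term addition from the candidate list and every single-term
deletion, takes the lowest-AIC move if it strictly improves the current
model, and stops otherwise. The result is locally AIC-optimal — no single
add or drop improves it — which is the guarantee the tests check; with
distinct AICs the result is invariant to candidate order, and exact ties go
to the earliest candidate in declared trait order. The search moves over
main effects; interaction models are fitted explicitly and compared in the
model table (formulas rendered with `+` and `×`).

**Canonical discriminant analysis.** With two groups there is a single
canonical axis: the leading eigenvector of W⁻¹B, with W and B the within-
and between-group scatter matrices of the included traits (by default all
15 minus swim factor, spawning-season length, and air breathing — three
traits that do not help separate the groups). Scores are centered at the
overall mean, scaled to unit pooled within-group variance, and signed so
the fast-group mean is positive. Structure coefficients are total-sample
Pearson correlations of each trait with the scores. The canonical
correlation satisfies the two-group identity r² = T²/(T² + n − 2) with
Hotelling's T², which the tests verify to 1e-8 against a from-scratch T².
A singular W is ridge-regularized (λ = 1e-8 × trace W) with a recorded
warning. Note the small-sample behavior: at n = 31 and p = 12 the *null*
median canonical correlation is ≈ 0.63 (T² ~ (n−2)p/(n−p−1)·F(p, n−p−1)),
so the absolute magnitude of r is not evidence of separation; the
permutation-calibration test checks the observed null against this F-based
prediction rather than against an arbitrary small bound.

## Synthetic data

`simulate_occurrences` plants isotropic bivariate-normal clusters
(dispersion in km, converted to degrees as 1/111.195 per km of latitude and
1/(111.195·cos φ) of longitude — adequate at Florida latitudes) plus
uniform noise points in a bounding box, and emits the planted memberships
and realized hull areas as ground truth. Planted points always carry
established status (so truth survives the status filter); noise points are
non-established with configurable probability.

`simulate_traits` draws the 15-trait schema: truncated normals for
continuous traits (bounded to each trait's documented range, targeting its
documented mean and SD), integer-uniform draws for ordinal traits, and
Bernoulli draws at the documented mean for binary traits (0.4 migratory,
0.3 air breathing — a fair coin would misstate both marginals). Trait
covariance is not modeled (identity structure); labels are Bernoulli with
logit = intercept + β·z over chosen per-sample-standardized traits, and the
true β is returned. Default study size is n = 31 species, matching the real
species list.

**What passing tests show — and don't.** The generators reproduce the
statistical skeleton the methods assume: compact occurrence clusters with
isolated noise, trait marginals on the documented ranges, a logistic
trait→label link. They deliberately omit geographic realism (coastlines,
hydrologic connectivity, record-density bias toward roads and cities) and
trait covariance. Passing planted-truth tests therefore establishes that
the *algorithms* are correct and well-calibrated at the study's sample
sizes, not that the ecological conclusions transfer to any particular real
extract.

## Problem sizes and determinism

Simulation-based tests use n = 31 species (the study size) with 100 seeded
replicates for selection-frequency and power checks, 200 seeded
configurations of ≤ 12 points for the clustering oracle, and 100 random
clouds for the hull-area oracle; parameter-recovery uses a single n = 5000
fit. All randomness flows through explicit integer seeds; reruns are
bit-identical.

## Known limitations

- Single-linkage chaining can merge two biologically distinct populations
  connected by a thin corridor of records; the 50-km threshold is a
  management choice, exposed as `link_km`.
- MCPs overestimate occupied habitat for concave ranges (coastlines);
  alpha hulls are a possible refinement, deliberately not implemented to
  keep the estimator conservative and comparable.
- Potential range treats thermal tolerance as the only range limit;
  salinity, hydrology, and biotic resistance are ignored.
- With n ≈ 31, stepwise selection and CDA overfit freely (see the null
  calibration above); reported models are descriptive, not confirmatory,
  and separated logistic fits have coefficients with no finite MLE.
- The establishment-status filter trusts the database's per-record status
  field; no reassessment of establishment is attempted.
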