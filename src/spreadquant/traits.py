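"""Trait statistics separating fast from slow spreaders.

Three complementary analyses on a table of life-history traits with a
binary fast/slow label:

* per-trait two-sided Mann–Whitney U tests (exact enumeration for small
  tie-free samples, tie-corrected normal approximation with continuity
  correction otherwise);
* logistic regression with bi-directional (add/drop) stepwise selection
  minimizing AIC;
* two-group canonical discriminant analysis (CDA), the eigen-analysis of
  within- vs. between-group scatter, reported as species scores on the
  single canonical axis plus structure coefficients (trait–axis
  correlations).

With ~31 species and interaction models, complete or quasi-complete
separation of the two groups is common; separated fits are returned with
a flag and a finite AIC rather than suppressed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

__all__ = [
    "TraitDef",
    "TRAITS",
    "TRAIT_NAMES",
    "DEFAULT_CDA_EXCLUDED",
    "UTestResult",
    "LogisticModel",
    "CanonicalResult",
    "validate_trait_table",
    "mann_whitney_u",
    "u_test_table",
    "design_matrix",
    "fit_logistic",
    "stepwise_aic",
    "model_comparison_table",
    "full_factorial",
    "main_effects",
    "canonical_discriminant",
]


@dataclass(frozen=True)
class TraitDef:
    """Schema entry for one life-history trait.

    ``kind`` is 'continuous', 'ordinal', or 'binary'; ``lo``/``hi`` bound
    the admissible values; ``mean``/``sd`` document the marginal observed
    across the 31 Florida species and parameterize the synthetic generator.
    """

    name: str
    label: str
    kind: str
    lo: float
    hi: float
    mean: float
    sd: float


#: The 15-trait life-history schema (units in the labels).
TRAITS: tuple[TraitDef, ...] = (
    TraitDef("max_length", "Maximum body length (cm TL)", "continuous", 6.0, 183.0, 41.8, 35.5),
    TraitDef("shape_factor", "Shape factor (TL / max body depth)", "continuous", 2.5, 18.5, 4.5, 3.0),
    TraitDef("swim_factor", "Swim factor (peduncle / caudal-fin depth)", "continuous", 0.3, 1.5, 0.6, 0.2),
    TraitDef("diet_breadth", "Diet breadth (1-7 food categories)", "ordinal", 1.0, 5.0, 2.7, 1.1),
    TraitDef("length_at_maturation", "Female length at maturation (cm)", "continuous", 2.3, 80.0, 16.5, 17.0),
    TraitDef("fecundity", "Fecundity (log10 eggs/season)", "continuous", 1.5, 4.9, 3.1, 0.8),
    TraitDef("egg_size", "Egg diameter (mm)", "continuous", 0.8, 9.0, 2.7, 2.2),
    TraitDef("spawning_temp", "Spawning temperature (°C)", "continuous", 20.0, 30.0, 24.8, 2.8),
    TraitDef("parental_care", "Parental care (Winemiller 0-6)", "ordinal", 0.0, 6.0, 4.6, 1.4),
    TraitDef("reproductive_guild", "Reproductive guild (0 nonguarder, 1 guarder, 2 livebearer)", "ordinal", 0.0, 2.0, 1.1, 0.4),
    TraitDef("time_to_hatch", "Time to hatch (h)", "continuous", 24.0, 1008.0, 173.4, 232.8),
    TraitDef("salinity_tolerance", "Salinity tolerance (0 none - 3 high)", "ordinal", 0.0, 3.0, 1.7, 1.1),
    TraitDef("spawning_season", "Spawning season length (months)", "ordinal", 2.0, 12.0, 6.8, 3.2),
    TraitDef("migratory", "Migratory (0/1)", "binary", 0.0, 1.0, 0.4, 0.5),
    TraitDef("air_breathing", "Air breathing (0/1)", "binary", 0.0, 1.0, 0.3, 0.5),
)

TRAIT_NAMES: tuple[str, ...] = tuple(t.name for t in TRAITS)

#: Traits dropped from CDA by default (uninformative for the fast/slow split).
DEFAULT_CDA_EXCLUDED: tuple[str, ...] = ("swim_factor", "spawning_season", "air_breathing")

_TRAIT_BY_NAME = {t.name: t for t in TRAITS}


def validate_trait_table(df: pd.DataFrame, traits: Sequence[str] = TRAIT_NAMES):
    """Validate a trait table against the schema.

    Returns ``(clean_df, excluded)`` where ``excluded`` maps species index
    labels with missing values to the offending columns; out-of-range
    values raise.
    """
    missing_cols = [t for t in traits if t not in df.columns]
    if missing_cols:
        raise ValueError(f"trait table missing columns: {missing_cols}")
    sub = df.loc[:, list(traits)].apply(pd.to_numeric, errors="coerce")
    excluded = {}
    for idx, row in sub.iterrows():
        gaps = list(row.index[row.isna()])
        if gaps:
            excluded[idx] = gaps
    clean = sub.drop(index=list(excluded))
    for name in traits:
        t = _TRAIT_BY_NAME.get(name)
        if t is None:
            continue
        col = clean[name]
        bad = col[(col < t.lo) | (col > t.hi)]
        if len(bad):
            raise ValueError(
                f"trait {name!r} out of range [{t.lo}, {t.hi}] for: {list(bad.index)}"
            )
    return clean, excluded


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------

#: Combined sample size at or below which the exact null distribution is used
#: (tie-free samples only).
EXACT_N_MAX = 12


@dataclass(frozen=True)
class UTestResult:
    trait: str
    u_statistic: float
    p_value: float
    n_fast: int
    n_slow: int
    method: str  # 'exact' or 'asymptotic'


def mann_whitney_u(
    fast_values, slow_values, trait: str = "", report_group: str = "fast"
) -> UTestResult:
    """Two-sided Mann–Whitney U test between fast and slow groups.

    The reported U is the fast group's statistic (rank-sum with midranks
    for ties). The exact permutation null is used when the combined sample
    is at most 12 with no ties; otherwise the normal approximation with
    tie correction and continuity correction.
    """
    fast = np.asarray(fast_values, dtype=float)
    slow = np.asarray(slow_values, dtype=float)
    if fast.size == 0 or slow.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([fast, slow])
    has_ties = len(np.unique(combined)) < combined.size
    if combined.size <= EXACT_N_MAX and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = scipy.stats.mannwhitneyu(
        fast, slow, alternative="two-sided", method=method, use_continuity=True
    )
    u_fast = float(res.statistic)
    u = u_fast if report_group == "fast" else fast.size * slow.size - u_fast
    return UTestResult(
        trait=trait,
        u_statistic=u,
        p_value=float(res.pvalue),
        n_fast=int(fast.size),
        n_slow=int(slow.size),
        method=method,
    )


def u_test_table(
    traits_df: pd.DataFrame, labels: pd.Series, traits: Sequence[str] = TRAIT_NAMES
) -> pd.DataFrame:
    """Per-trait U tests; ``labels`` is boolean/0-1 with 1 = fast."""
    lab = np.asarray(labels).astype(bool)
    rows = []
    for name in traits:
        r = mann_whitney_u(
            traits_df.loc[lab, name], traits_df.loc[~lab, name], trait=name
        )
        rows.append(
            {
                "trait": name,
                "u_statistic": r.u_statistic,
                "p_value": r.p_value,
                "method": r.method,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Logistic regression and stepwise AIC
# ---------------------------------------------------------------------------

Term = tuple[str, ...]  # interaction term as a tuple of trait names


def _term_label(term: Term) -> str:
    return " × ".join(term)


def main_effects(*names: str) -> list[Term]:
    """Model spec with one main-effect term per trait name."""
    return [(n,) for n in names]


def full_factorial(*names: str) -> list[Term]:
    """All main effects and interactions of the given traits (a×b×c style)."""
    terms: list[Term] = []
    for k in range(1, len(names) + 1):
        terms.extend(itertools.combinations(names, k))
    return terms


def design_matrix(traits_df: pd.DataFrame, terms: Iterable[Term]) -> pd.DataFrame:
    """Design matrix with an intercept column; interactions are products."""
    cols = {"(Intercept)": np.ones(len(traits_df))}
    for term in terms:
        col = np.ones(len(traits_df))
        for name in term:
            col = col * traits_df[name].to_numpy(dtype=float)
        cols[_term_label(term)] = col
    return pd.DataFrame(cols, index=traits_df.index)


@dataclass
class LogisticModel:
    """A fitted binomial-logit model."""

    terms: tuple[Term, ...]
    coef: pd.Series
    llf: float
    aic: float
    converged: bool
    separation: bool
    rank_deficient: bool
    n_obs: int
    label_sum: int

    @property
    def formula(self) -> str:
        if not self.terms:
            return "spread group ~ 1"
        return "spread group ~ " + " + ".join(_term_label(t) for t in self.terms)

    def predict(self, traits_df: pd.DataFrame) -> np.ndarray:
        X = design_matrix(traits_df, self.terms)
        eta = X.to_numpy() @ self.coef.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))


#: |linear predictor| beyond which a fitted probability is numerically 0/1.
_ETA_PINNED = 30.0


def fit_logistic(
    labels, traits_df: pd.DataFrame | None = None, terms: Iterable[Term] = ()
) -> LogisticModel:
    """Maximum-likelihood logistic fit of fast/slow labels on trait terms.

    ``terms`` is a list of trait-name tuples (singletons are main effects,
    longer tuples interaction products); the intercept is always included.
    Complete/quasi-complete separation is detected (diverging coefficients
    pin fitted probabilities at 0/1) and flagged; the model is still
    returned with its log-likelihood and AIC = 2k − 2·logL.
    """
    y = np.asarray(labels).astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    terms = tuple(tuple(t) for t in terms)
    if traits_df is None:
        if terms:
            raise ValueError("terms given without a trait table")
        traits_df = pd.DataFrame(index=pd.RangeIndex(len(y)))
    X = design_matrix(traits_df, terms)
    rank_deficient = np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]

    caught: list[warnings.WarningMessage] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, X.to_numpy()).fit(
                method="newton", maxiter=200, tol=1e-10, disp=0
            )
            params = np.asarray(fit.params, dtype=float)
            converged = bool(fit.mle_retvals.get("converged", True))
        except np.linalg.LinAlgError:  # singular hessian: fall back to IRLS
            fit = sm.GLM(y, X.to_numpy(), family=sm.families.Binomial()).fit(maxiter=500)
            params = np.asarray(fit.params, dtype=float)
            converged = bool(getattr(fit, "converged", True))

    warned_separation = any(
        issubclass(w.category, PerfectSeparationWarning) for w in caught
    )
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        converged = False

    eta = X.to_numpy() @ params
    separation = warned_separation or bool(np.abs(eta).max(initial=0.0) > _ETA_PINNED)
    # Log-likelihood from clipped fitted probabilities: finite even when
    # separation pins probabilities at exactly 0/1 (supremum llf -> 0).
    p = np.clip(1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500))), 1e-300, 1 - 1e-16)
    llf = float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))

    k = X.shape[1]
    aic = 2.0 * k - 2.0 * llf
    coef = pd.Series(params, index=list(X.columns))
    return LogisticModel(
        terms=terms,
        coef=coef,
        llf=llf,
        aic=float(aic),
        converged=converged,
        separation=separation,
        rank_deficient=rank_deficient,
        n_obs=int(len(y)),
        label_sum=int(y.sum()),
    )


def stepwise_aic(
    labels,
    traits_df: pd.DataFrame,
    candidates: Sequence[str] | None = None,
    start: Iterable[Term] = (),
    direction: str = "both",
) -> LogisticModel:
    """Greedy bi-directional stepwise logistic model selection by AIC.

    From ``start`` (default intercept-only), every single-term addition
    (from ``candidates``, in declared order) and deletion is evaluated
    each step; the move with the lowest AIC is taken if it improves on the
    current model, ties broken by evaluation order. Stops when no move
    lowers the AIC, so the returned model is locally AIC-optimal.
    """
    if direction not in ("both", "forward", "backward"):
        raise ValueError(f"unknown direction: {direction!r}")
    if candidates is None:
        candidates = [c for c in traits_df.columns if c in _TRAIT_BY_NAME]
    if not candidates:
        raise ValueError("candidate set is empty")
    current_terms = [tuple(t) for t in start]
    current = fit_logistic(labels, traits_df, current_terms)
    history = [current]
    while True:
        moves: list[list[Term]] = []
        if direction in ("both", "forward"):
            for name in candidates:
                if (name,) not in current_terms:
                    moves.append(current_terms + [(name,)])
        if direction in ("both", "backward"):
            for term in current_terms:
                moves.append([t for t in current_terms if t != term])
        best = None
        for terms in moves:
            cand = fit_logistic(labels, traits_df, terms)
            if best is None or cand.aic < best.aic:  # strict: earliest wins ties
                best = cand
        if best is None or best.aic >= current.aic:
            break
        current = best
        current_terms = list(best.terms)
        history.append(best)
    current.history = history  # type: ignore[attr-defined]
    return current


def model_comparison_table(models: Sequence[LogisticModel]) -> pd.DataFrame:
    """Rank fitted models by AIC (ascending), Table-3 style formulas.

    All models must have been fitted on the same observations.
    """
    if not models:
        raise ValueError("no models to compare")
    sig = {(m.n_obs, m.label_sum) for m in models}
    if len(sig) > 1:
        raise ValueError(f"models fitted on differing observation sets: {sorted(sig)}")
    rows = [
        {
            "model": m.formula,
            "aic": m.aic,
            "k": len(m.coef),
            "log_likelihood": m.llf,
            "separation": m.separation,
            "converged": m.converged,
        }
        for m in models
    ]
    return (
        pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Canonical discriminant analysis
# ---------------------------------------------------------------------------


@dataclass
class CanonicalResult:
    """Two-group CDA on one canonical axis."""

    scores: pd.Series  # per species, overall mean 0, fast mean > 0
    structure: pd.Series  # trait–score Pearson correlations
    canonical_correlation: float
    eigenvalue: float
    traits: tuple[str, ...]
    warnings: list = field(default_factory=list)


def canonical_discriminant(
    traits_df: pd.DataFrame,
    labels,
    exclude: Sequence[str] = DEFAULT_CDA_EXCLUDED,
) -> CanonicalResult:
    """Canonical discriminant analysis of traits against fast/slow labels.

    With two groups there is a single canonical axis: the leading
    eigenvector of W⁻¹B, where W and B are the within- and between-group
    scatter matrices. Scores are centered at the overall mean and scaled
    to unit pooled within-group variance; the sign convention puts the
    fast-group mean above zero. Structure coefficients are the Pearson
    correlations of each input trait with the scores. A singular W is
    ridge-regularized (λ = 1e-8 × trace W) with a warning recorded.
    """
    lab = np.asarray(labels).astype(bool)
    included = [c for c in traits_df.columns if c not in set(exclude)]
    if len(included) == 0:
        raise ValueError("no traits left after exclusions")
    if lab.sum() < 2 or (~lab).sum() < 2:
        raise ValueError("need at least 2 species per group")
    X = traits_df.loc[:, included].to_numpy(dtype=float)
    n, p = X.shape
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for g in (lab, ~lab):
        Xg = X[g]
        mg = Xg.mean(axis=0)
        dev = Xg - mg
        W += dev.T @ dev
        dg = (mg - grand)[:, None]
        B += len(Xg) * (dg @ dg.T)

    notes = []
    try:
        M = np.linalg.solve(W, B)
    except np.linalg.LinAlgError:
        lam = 1e-8 * np.trace(W)
        notes.append(f"singular within-group scatter; ridge λ={lam:.3e} applied")
        M = np.linalg.solve(W + lam * np.eye(p), B)
    evals, evecs = np.linalg.eig(M)
    order = np.argsort(evals.real)[::-1]
    lam1 = float(evals.real[order[0]])
    v = evecs[:, order[0]].real

    raw = (X - grand) @ v
    # Unit pooled within-group variance of the scores.
    ssw = sum(((raw[g] - raw[g].mean()) ** 2).sum() for g in (lab, ~lab))
    scale = np.sqrt(ssw / (n - 2)) if ssw > 0 else 1.0
    scores = raw / scale
    if scores[lab].mean() < 0:
        scores = -scores
    scores = pd.Series(scores, index=traits_df.index, name="canonical_score")

    structure = pd.Series(
        {
            name: float(np.corrcoef(traits_df[name].to_numpy(dtype=float), scores)[0, 1])
            for name in included
        },
        name="structure_coefficient",
    )
    r = float(np.sqrt(max(lam1, 0.0) / (1.0 + max(lam1, 0.0))))
    return CanonicalResult(
        scores=scores,
        structure=structure,
        canonical_correlation=r,
        eigenvalue=lam1,
        traits=tuple(included),
        warnings=notes,
    )
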