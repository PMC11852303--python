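"""Trait statistics: U tests, logistic/stepwise AIC, and CDA, each checked
against an independent oracle (enumeration, closed form, or Hotelling T²)."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import spreadquant as sq
from spreadquant.traits import (
    TRAIT_NAMES,
    design_matrix,
    full_factorial,
    main_effects,
    validate_trait_table,
)

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def enumerate_u_pvalue(fast, slow):
    """Exact two-sided p by enumerating all group assignments of the pooled
    sample (tie-free data): the U statistic's full permutation null."""
    pooled = np.concatenate([fast, slow])
    n1 = len(fast)

    def u_of(f_idx):
        f = pooled[list(f_idx)]
        s = np.delete(pooled, list(f_idx))
        return sum((fi > si) for fi in f for si in s)

    u_obs = u_of(range(n1))
    mid = n1 * (len(pooled) - n1) / 2.0
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), n1)]
    return np.mean([abs(u - mid) >= abs(u_obs - mid) for u in us])


def hotelling_t2(X, labels):
    """Two-sample Hotelling T² from first principles."""
    g = np.asarray(labels).astype(bool)
    X1, X0 = X[g], X[~g]
    n1, n0 = len(X1), len(X0)
    d = X1.mean(axis=0) - X0.mean(axis=0)
    S = (
        (X1 - X1.mean(0)).T @ (X1 - X1.mean(0))
        + (X0 - X0.mean(0)).T @ (X0 - X0.mean(0))
    ) / (n1 + n0 - 2)
    return float(n1 * n0 / (n1 + n0) * d @ np.linalg.solve(S, d))


def _sim_traits(seed, n=31, beta=None):
    spec = sq.TraitSimSpec(n_species=n, beta=beta or {})
    return sq.simulate_traits(spec, seed=seed)


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------


def test_u_small_sample_exact_matches_enumeration():
    fast, slow = [3.0, 4.0], [1.0, 2.0]
    res = sq.mann_whitney_u(fast, slow)
    assert res.method == "exact"
    assert res.u_statistic == 4
    assert res.p_value == pytest.approx(1 / 3, abs=1e-12)
    assert res.p_value == pytest.approx(enumerate_u_pvalue(fast, slow), abs=1e-12)


def test_u_exact_path_matches_enumeration_on_random_samples():
    rng = np.random.default_rng(17)
    for _ in range(20):
        n1, n2 = rng.integers(2, 7), rng.integers(2, 7)
        pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free
        fast, slow = pooled[:n1], pooled[n1:]
        res = sq.mann_whitney_u(fast, slow)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(enumerate_u_pvalue(fast, slow), abs=1e-12)


def test_u_identical_groups_with_midranks():
    res = sq.mann_whitney_u([1, 2, 3], [1, 2, 3])
    assert res.u_statistic == 4.5  # n1·n2/2 with midranks
    assert res.method == "asymptotic"  # ties force the approximation


def test_u_complementarity_identity():
    rng = np.random.default_rng(23)
    fast, slow = rng.normal(size=13), rng.normal(size=18)
    r_fast = sq.mann_whitney_u(fast, slow)
    r_slow = sq.mann_whitney_u(fast, slow, report_group="slow")
    assert r_fast.u_statistic + r_slow.u_statistic == 13 * 18
    assert 0 <= r_fast.u_statistic <= 13 * 18


def test_u_empty_group_rejected():
    with pytest.raises(ValueError):
        sq.mann_whitney_u([], [1.0])


def test_u_exact_and_asymptotic_agree_for_moderate_n():
    """The normal approximation is within 0.02 of the exact p at n1=n2=6."""
    rng = np.random.default_rng(31)
    for _ in range(10):
        pooled = rng.permutation(np.arange(1.0, 13.0))
        fast, slow = pooled[:6], pooled[6:]
        exact = scipy.stats.mannwhitneyu(fast, slow, alternative="two-sided", method="exact")
        approx = scipy.stats.mannwhitneyu(
            fast, slow, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        assert abs(exact.pvalue - approx.pvalue) < 0.02


def test_u_table_runs_all_traits():
    df, labels, _ = _sim_traits(seed=5)
    table = sq.u_test_table(df, labels)
    assert list(table["trait"]) == list(TRAIT_NAMES)
    assert ((table["p_value"] >= 0) & (table["p_value"] <= 1)).all()


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------


def test_intercept_only_fit_matches_bernoulli_closed_form():
    y = np.r_[np.ones(10), np.zeros(10)]
    m = sq.fit_logistic(y)
    assert m.coef["(Intercept)"] == pytest.approx(0.0, abs=1e-8)
    assert m.llf == pytest.approx(20 * np.log(0.5), rel=1e-10)
    assert m.aic == pytest.approx(2 - 2 * 20 * np.log(0.5), rel=1e-10)


def test_aic_definitional_identity_on_assorted_models():
    df, labels, _ = _sim_traits(seed=2)
    for terms in ([], main_effects("max_length"), full_factorial("max_length", "diet_breadth")):
        m = sq.fit_logistic(labels, df, terms)
        assert m.aic == pytest.approx(2 * len(m.coef) - 2 * m.llf, abs=1e-10)


def test_parameter_recovery_large_sample():
    """With n=5000 and a known (β0, β1), the MLE lands within 3 SE."""
    rng = np.random.default_rng(123)
    x = rng.normal(size=5000)
    eta = -1.0 + 0.8 * x
    y = (rng.random(5000) < 1 / (1 + np.exp(-eta))).astype(float)
    df = pd.DataFrame({"max_length": x})
    m = sq.fit_logistic(y, df, main_effects("max_length"))
    # Fisher information SEs at the truth are ~0.04; use a generous 3×0.06
    assert m.coef["(Intercept)"] == pytest.approx(-1.0, abs=0.18)
    assert m.coef["max_length"] == pytest.approx(0.8, abs=0.18)
    assert m.converged and not m.separation


def test_separation_is_flagged_not_fatal():
    y = np.r_[np.zeros(5), np.ones(5)]
    df = pd.DataFrame({"max_length": np.arange(10.0)})
    m = sq.fit_logistic(y, df, main_effects("max_length"))
    assert m.separation
    assert np.isfinite(m.aic)


def test_single_class_labels_rejected():
    with pytest.raises(ValueError):
        sq.fit_logistic(np.ones(8))


def test_rank_deficient_design_is_reported():
    y = np.r_[np.zeros(8), np.ones(8)]
    rng = np.random.default_rng(0)
    col = rng.normal(size=16)
    df = pd.DataFrame({"max_length": col, "shape_factor": 2 * col})
    m = sq.fit_logistic(y, df, main_effects("max_length", "shape_factor"))
    assert m.rank_deficient


def test_irls_deviance_decreases_monotonically():
    """On non-separated data, each IRLS iterate improves the deviance."""
    import statsmodels.api as sm

    rng = np.random.default_rng(7)
    x = rng.normal(size=200)
    y = (rng.random(200) < 1 / (1 + np.exp(-(0.3 + 0.7 * x)))).astype(float)
    X = sm.add_constant(x)
    deviances = []
    for k in range(1, 8):
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=k)
        deviances.append(fit.deviance)
    assert all(b <= a + 1e-10 for a, b in zip(deviances, deviances[1:]))


def test_interaction_design_columns_are_products():
    df, labels, _ = _sim_traits(seed=4, n=12)
    X = design_matrix(df, full_factorial("max_length", "diet_breadth"))
    np.testing.assert_allclose(
        X["max_length × diet_breadth"], df["max_length"] * df["diet_breadth"]
    )
    assert list(X.columns) == [
        "(Intercept)", "max_length", "diet_breadth", "max_length × diet_breadth"
    ]


# ---------------------------------------------------------------------------
# stepwise AIC
# ---------------------------------------------------------------------------


def test_stepwise_result_is_locally_aic_optimal():
    """No single add or drop improves the returned model, even on pure
    noise where greedy selection may still pick spurious terms."""
    df, labels, _ = _sim_traits(seed=11)  # β = 0: labels independent of traits
    best = sq.stepwise_aic(labels, df)
    terms = list(best.terms)
    for name in TRAIT_NAMES:
        if (name,) not in terms:
            alt = sq.fit_logistic(labels, df, terms + [(name,)])
            assert alt.aic >= best.aic - 1e-9
    for term in terms:
        alt = sq.fit_logistic(labels, df, [t for t in terms if t != term])
        assert alt.aic >= best.aic - 1e-9


def test_stepwise_never_worse_than_start():
    df, labels, _ = _sim_traits(seed=13)
    null = sq.fit_logistic(labels, df, [])
    best = sq.stepwise_aic(labels, df)
    assert best.aic <= null.aic


def test_stepwise_selects_planted_strong_predictor():
    """A strong planted effect on maximum length at n=31 is found in at
    least 90 of 100 seeded replicates."""
    hits = 0
    for seed in range(100):
        df, labels, _ = _sim_traits(seed=seed, beta={"max_length": 2.5})
        if labels.sum() < 2 or (1 - labels).sum() < 2:
            continue  # degenerate draw: all one class
        best = sq.stepwise_aic(labels, df)
        hits += ("max_length",) in best.terms
    assert hits >= 90


def test_model_comparison_sorted_and_guarded():
    df, labels, _ = _sim_traits(seed=3)
    m1 = sq.fit_logistic(labels, df, [])
    m2 = sq.fit_logistic(labels, df, main_effects("max_length"))
    m3 = sq.fit_logistic(labels, df, main_effects("max_length", "diet_breadth"))
    table = sq.model_comparison_table([m1, m2, m3])
    assert list(table["aic"]) == sorted(table["aic"])
    assert table.loc[0, "model"].startswith("spread group ~ ")
    single = sq.model_comparison_table([m1])
    assert len(single) == 1
    other = sq.fit_logistic(labels.iloc[:20], df.iloc[:20], [])
    with pytest.raises(ValueError, match="differing observation"):
        sq.model_comparison_table([m1, other])


def test_comparison_ranks_true_model_above_null_on_planted_data():
    df, labels, _ = _sim_traits(seed=19, n=200, beta={"max_length": 1.5})
    null = sq.fit_logistic(labels, df, [])
    true = sq.fit_logistic(labels, df, main_effects("max_length"))
    table = sq.model_comparison_table([null, true])
    assert table.loc[0, "model"] == "spread group ~ max_length"


# ---------------------------------------------------------------------------
# canonical discriminant analysis
# ---------------------------------------------------------------------------


def test_cda_single_trait_structure_is_unit():
    df = pd.DataFrame({"max_length": [1.0, 2.0, 3.0, 11.0, 12.0, 13.0]})
    labels = [0, 0, 0, 1, 1, 1]
    res = sq.canonical_discriminant(df, labels, exclude=())
    assert abs(res.structure["max_length"]) == pytest.approx(1.0, abs=1e-10)


def test_cda_satisfies_hotelling_identity():
    """canonical r² = T²/(T² + n − 2) for two groups."""
    df, labels, _ = _sim_traits(seed=29)
    res = sq.canonical_discriminant(df, labels)
    X = df.loc[:, list(res.traits)].to_numpy(dtype=float)
    t2 = hotelling_t2(X, labels)
    n = len(df)
    assert res.canonical_correlation**2 == pytest.approx(t2 / (t2 + n - 2), abs=1e-8)


def test_cda_scores_centered_and_fast_positive():
    df, labels, _ = _sim_traits(seed=37, beta={"max_length": 2.0})
    res = sq.canonical_discriminant(df, labels)
    assert res.scores.mean() == pytest.approx(0.0, abs=1e-9)
    assert res.scores[labels.astype(bool).to_numpy()].mean() > 0
    assert ((res.structure >= -1) & (res.structure <= 1)).all()


def test_cda_scores_invariant_to_affine_trait_rescaling():
    df, labels, _ = _sim_traits(seed=41)
    base = sq.canonical_discriminant(df, labels)
    rescaled = df.copy()
    rescaled["max_length"] = 5.0 * rescaled["max_length"] - 100.0
    rescaled["fecundity"] = 0.1 * rescaled["fecundity"] + 3.0
    res = sq.canonical_discriminant(rescaled, labels)
    np.testing.assert_allclose(res.scores, base.scores, atol=1e-6)


def test_cda_excludes_default_traits():
    df, labels, _ = _sim_traits(seed=43)
    res = sq.canonical_discriminant(df, labels)
    assert set(res.traits) == set(TRAIT_NAMES) - {
        "swim_factor", "spawning_season", "air_breathing"
    }


def test_cda_permuted_labels_match_null_calibration():
    """Under label permutation the canonical correlation follows its
    Hotelling null: T² ~ (n−2)p/(n−p−1) · F(p, n−p−1), r² = T²/(T²+n−2).
    At n=31, p=12 the null median r is ≈ 0.63 — large in absolute terms
    (heavy small-sample overfitting), and the permutation median should
    sit at that null value, not above it."""
    df, labels, _ = _sim_traits(seed=47, beta={"max_length": 2.0})
    n, p = len(df), 12
    f_med = scipy.stats.f.median(p, n - p - 1)
    t2_med = (n - 2) * p / (n - p - 1) * f_med
    r_null = np.sqrt(t2_med / (t2_med + n - 2))
    rng = np.random.default_rng(0)
    rs = []
    for _ in range(200):
        perm = rng.permutation(labels.to_numpy())
        if perm.sum() < 2 or (1 - perm).sum() < 2:
            continue
        rs.append(sq.canonical_discriminant(df, perm).canonical_correlation)
    assert np.median(rs) == pytest.approx(r_null, abs=0.08)


def test_cda_requires_two_per_group():
    df, _, _ = _sim_traits(seed=1, n=5)
    with pytest.raises(ValueError):
        sq.canonical_discriminant(df, [1, 0, 0, 0, 0])


# ---------------------------------------------------------------------------
# trait table validation
# ---------------------------------------------------------------------------


def test_validate_reports_missing_and_rejects_out_of_range():
    df, _, _ = _sim_traits(seed=53, n=6)
    df.iloc[2, df.columns.get_loc("egg_size")] = np.nan
    clean, excluded = validate_trait_table(df)
    assert list(excluded) == [df.index[2]]
    assert len(clean) == 5
    bad = df.dropna().copy()
    bad.iloc[0, bad.columns.get_loc("max_length")] = 500.0
    with pytest.raises(ValueError, match="max_length"):
        validate_trait_table(bad)
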