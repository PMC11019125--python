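"""OLS age models, FDR adjustment and the metadata screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dogclock.association import (
    RankDeficientDesignError,
    associate_features,
    bh_adjust,
    build_age_design,
    classify_direction,
    fit_feature_age_models,
    ols_fit,
    screen_metadata_age,
)
from dogclock.config import SimulationConfig
from dogclock.features import FeatureMatrix
from dogclock.simulate import CELL_CD8, simulate_cohort


def test_ols_noiseless_recovery():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(15, 2))
    y = X @ np.array([2.0, 3.0])
    fit = ols_fit(y, X)
    np.testing.assert_allclose(fit.params, [2.0, 3.0], atol=1e-10)
    np.testing.assert_allclose(fit.residuals, 0, atol=1e-10)
    assert fit.r2 == pytest.approx(1.0)


def test_ols_intercept_only_gives_mean():
    y = np.array([1.0, 4.0, 7.0, 8.0])
    fit = ols_fit(y, np.ones((4, 1)))
    assert fit.params[0] == pytest.approx(y.mean())


def test_ols_matches_statsmodels():
    import statsmodels.api as sm

    rng = np.random.default_rng(1)
    X = np.column_stack([np.ones(20), rng.normal(size=(20, 2))])
    y = rng.normal(size=20)
    mine = ols_fit(y, X)
    ref = sm.OLS(y, X).fit()
    np.testing.assert_allclose(mine.params, ref.params, atol=1e-10)
    np.testing.assert_allclose(mine.bse, ref.bse, atol=1e-10)
    np.testing.assert_allclose(mine.pvalues, ref.pvalues, atol=1e-10)
    assert mine.r2 == pytest.approx(ref.rsquared)
    assert mine.r2_adj == pytest.approx(ref.rsquared_adj)


def test_ols_matches_normal_equations():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(20, 3))
    y = rng.normal(size=20)
    fit = ols_fit(y, X)
    beta = np.linalg.inv(X.T @ X) @ X.T @ y
    np.testing.assert_allclose(fit.params, beta, atol=1e-10)


def test_ols_rank_deficiency_names_columns():
    X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
    # x1 and x2 are mutually dependent; either may be reported
    with pytest.raises(RankDeficientDesignError, match="x1|x2"):
        ols_fit(np.zeros(10), X)


def _feature_matrix(meta, arrays, kind="atac"):
    values = pd.DataFrame(
        np.column_stack(arrays),
        index=meta["sample_id"],
        columns=[f"f{i}" for i in range(len(arrays))],
    )
    return FeatureMatrix(values=values, kind=kind)


@pytest.fixture(scope="module")
def cohort():
    meta, _ = simulate_cohort(SimulationConfig(n_samples=60, seed=11))
    return meta


def test_perfect_age_signal_detected(cohort):
    age = cohort["age"].to_numpy(dtype=float)
    rng = np.random.default_rng(3)
    fm = _feature_matrix(cohort, [age * 0.5, rng.normal(size=len(age))])
    res = associate_features(fm, cohort)
    f0 = res.set_index("feature_id").loc["f0"]
    assert f0["p"] < 1e-20
    assert f0["direction"] == "increasing"


def test_cell_proxy_feature_absorbed_by_covariate(cohort):
    """A feature tracking the CD8 proportion shows no age effect once the
    covariate is in the model, although marginally (no covariate) it is
    clearly age-correlated."""
    rng = np.random.default_rng(4)
    cd8 = cohort[CELL_CD8].to_numpy(dtype=float)
    age = cohort["age"].to_numpy(dtype=float)
    feature = cd8 + rng.normal(0, 1.0, size=len(cd8))
    fm = _feature_matrix(cohort, [feature])
    res = fit_feature_age_models(fm, cohort)
    # no-covariate fit: feature ~ age alone
    marginal = ols_fit(feature, np.column_stack([np.ones(len(age)), age]))
    assert marginal.pvalues[1] < 1e-4
    assert res.loc[0, "p"] > 0.05
    assert res.loc[0, "p"] > marginal.pvalues[1]


def test_zero_variance_feature_gets_p_one(cohort):
    fm = _feature_matrix(cohort, [np.zeros(len(cohort))])
    res = fit_feature_age_models(fm, cohort)
    assert res.loc[0, "p"] == 1.0
    assert res.loc[0, "beta_age"] == 0.0


def test_missing_covariate_errors_before_fit(cohort):
    fm = _feature_matrix(cohort, [np.arange(len(cohort), dtype=float)])
    broken = cohort.drop(columns=[CELL_CD8])
    with pytest.raises(ValueError, match="cell.CD8"):
        fit_feature_age_models(fm, broken)


def test_vectorized_fit_matches_single_ols(cohort):
    rng = np.random.default_rng(5)
    arrays = [rng.normal(size=len(cohort)) for _ in range(4)]
    fm = _feature_matrix(cohort, arrays)
    res = fit_feature_age_models(fm, cohort)
    X, names, age_ix = build_age_design(cohort)
    for i, y in enumerate(arrays):
        single = ols_fit(y, X, names)
        assert res.loc[i, "beta_age"] == pytest.approx(single.params[age_ix], abs=1e-10)
        assert res.loc[i, "p"] == pytest.approx(single.pvalues[age_ix], abs=1e-10)


def _bh_brute_force(p):
    """Literal step-up definition: q_(i) = min_{j>=i} (m/j) p_(j), capped."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [m * p[order[j]] / (j + 1) for j in range(rank_pos, m)]
        q[idx] = min(1.0, min(candidates))
    return q


@pytest.mark.parametrize(
    "p,expected",
    [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.5, 0.5, 0.5], [0.5, 0.5, 0.5]),
        ([0.07], [0.07]),
    ],
)
def test_bh_known_values(p, expected):
    np.testing.assert_allclose(bh_adjust(np.array(p)), expected, atol=1e-12)


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(6)
    for _ in range(20):
        p = rng.uniform(size=int(rng.integers(1, 50)))
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )
        np.testing.assert_allclose(
            bh_adjust(p, method="by"), multipletests(p, method="fdr_by")[1], atol=1e-12
        )


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
def test_bh_properties(p):
    p = np.array(p)
    q = bh_adjust(p)
    assert (q >= p - 1e-15).all()
    assert (q <= 1.0).all()
    order = np.argsort(p, kind="mergesort")
    assert (np.diff(q[order]) >= -1e-12).all()  # monotone in p
    np.testing.assert_allclose(q, _bh_brute_force(p), atol=1e-12)


def test_bh_rejects_invalid_p():
    with pytest.raises(ValueError):
        bh_adjust(np.array([0.5, 1.2]))


def test_direction_classification():
    res = pd.DataFrame({"beta_age": [0.5, -0.5, -0.5], "q": [0.01, 0.2, 0.001]})
    labels = classify_direction(res)
    assert labels.tolist() == ["increasing", "ns", "decreasing"]


def test_screen_flags_designated_cell_types_only():
    meta, truth = simulate_cohort(SimulationConfig(n_samples=500, seed=13))
    screen = screen_metadata_age(meta)
    sig = set(screen.loc[screen["q"] < 0.05, "variable"])
    assert set(truth.true_cell_slopes) <= sig
    null_cells = {v for v in screen["variable"] if v.startswith("cell.")} - set(
        truth.true_cell_slopes
    )
    # null cell types should mostly stay below threshold
    assert len(sig & null_cells) <= max(2, int(0.05 * len(null_cells)) + 2)
    # exercise was generated age-dependent: the ANOVA should notice at n=500
    assert "exercise" in sig


def test_anova_identical_group_means_null():
    meta = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(9)],
            "age": [5.0, 6.0, 7.0] * 3,
            "exercise": ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
        }
    )
    screen = screen_metadata_age(meta, categorical=("exercise",))
    row = screen.set_index("variable").loc["exercise"]
    assert row["stat"] == pytest.approx(0.0, abs=1e-12)
    assert row["p"] == pytest.approx(1.0)


def test_anova_two_groups_equals_t_squared():
    rng = np.random.default_rng(7)
    ages = rng.normal(10, 3, size=30)
    groups = np.array(["x"] * 15 + ["y"] * 15)
    meta = pd.DataFrame({"sample_id": [f"s{i}" for i in range(30)], "age": ages, "g": groups})
    screen = screen_metadata_age(meta, categorical=("g",))
    f_val = screen.set_index("variable").loc["g", "stat"]
    t_val = stats.ttest_ind(ages[:15], ages[15:]).statistic
    assert f_val == pytest.approx(t_val**2, rel=1e-10)


def test_screen_skips_single_level_category():
    meta = pd.DataFrame(
        {"sample_id": ["a", "b", "c"], "age": [1.0, 2.0, 3.0], "g": ["x", "x", "x"]}
    )
    screen = screen_metadata_age(meta, categorical=("g",))
    assert "g" not in screen["variable"].tolist()


def test_atac_effect_recovery_correlates_with_truth():
    """With many samples and strong slopes, per-feature OLS age effects on
    the log-RPKM scale correlate strongly with the generative slopes."""
    from dogclock.atac import process_atac
    from dogclock.simulate import simulate_atac

    cfg = SimulationConfig(
        n_samples=400, n_atac_peaks=400, frac_age_assoc_atac=0.5,
        atac_age_slope_sd=0.08, n_decoy_features=0, seed=17,
    )
    meta, _ = simulate_cohort(cfg)
    atac, truth = simulate_atac(meta, cfg)
    fm, retained = process_atac(atac.peaks, atac.counts)
    res = fit_feature_age_models(fm, meta).set_index("feature_id")
    common = [f for f in truth.age_assoc_atac_ids if f in res.index]
    est = res.loc[common, "beta_age"].to_numpy()
    true = np.array([truth.true_slopes[f] for f in common])
    assert np.corrcoef(est, true)[0, 1] > 0.9


def test_beta_age_unbiased_over_replicates():
    """Mean estimation error of the age effect stays within its Monte-Carlo
    confidence band over 200 simulated-feature replicates."""
    meta, _ = simulate_cohort(SimulationConfig(n_samples=40, seed=19))
    age = meta["age"].to_numpy(dtype=float)
    rng = np.random.default_rng(20)
    true_slope = 0.3
    errors = []
    for _ in range(200):
        y = true_slope * age + rng.normal(0, 1.0, size=len(age))
        fm = _feature_matrix(meta, [y])
        res = fit_feature_age_models(fm, meta)
        errors.append(res.loc[0, "beta_age"] - true_slope)
    errors = np.array(errors)
    assert abs(errors.mean()) < 3 * errors.std(ddof=1) / np.sqrt(len(errors))
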