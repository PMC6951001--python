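import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import naive_reference as ref
from t1quant import (
    CohortAnalysis,
    CohortSimSpec,
    diagnostic_metrics,
    generate_cohort,
    multivariate_t1_model,
    roc_analysis,
    route_and_compare,
    univariate_screen,
)


# --- routing -----------------------------------------------------------------

def test_normal_samples_route_to_t_test():
    rng = np.random.default_rng(0)
    res = route_and_compare(
        np.r_[rng.normal(0, 1, 60), rng.normal(1, 1, 60)],
        np.r_[["a"] * 60, ["b"] * 60],
    )
    assert res.test_used == "T_TEST"
    assert res.p_value < 0.05
    assert "mean" in next(iter(res.group_summaries.values()))


def test_heavy_tailed_samples_route_to_mann_whitney():
    rng = np.random.default_rng(1)
    values = np.r_[rng.lognormal(0, 1.5, 100), rng.lognormal(0, 1.5, 100)]
    res = route_and_compare(values, np.r_[["a"] * 100, ["b"] * 100])
    assert res.test_used == "MANN_WHITNEY"
    assert "median" in next(iter(res.group_summaries.values()))


def test_published_mvo_contingency_routes_to_chi_squared():
    # incidence 6/15 vs 11/13: all expected cells >= 5 -> chi-squared, p < .05
    values = np.r_[np.repeat(True, 6), np.repeat(False, 9), np.repeat(True, 11), np.repeat(False, 2)]
    labels = np.r_[["low"] * 15, ["high"] * 13]
    res = route_and_compare(values, labels, "categorical")
    assert res.test_used == "CHI_SQ"
    assert res.p_value < 0.05


def test_small_expected_cells_route_to_fisher():
    values = np.r_[np.repeat(True, 1), np.repeat(False, 9), np.repeat(True, 8), np.repeat(False, 2)]
    labels = np.r_[["a"] * 10, ["b"] * 10]
    res = route_and_compare(values, labels, "categorical")
    assert res.test_used == "FISHER"


def test_identical_constant_samples_compare_equal():
    res = route_and_compare([5.0] * 10 + [5.0] * 10, ["a"] * 10 + ["b"] * 10)
    assert res.p_value == 1.0


def test_empty_group_is_an_error():
    with pytest.raises(ValueError):
        route_and_compare([1.0, 2.0], ["a", "a"])


def test_type_one_error_calibrated_on_both_routes():
    # under the null, rejection at alpha=.05 must land in [0.03, 0.07]
    rng = np.random.default_rng(2024)
    labels = np.r_[["a"] * 50, ["b"] * 50]
    for generator in (
        lambda: rng.normal(0, 1, 100),
        lambda: rng.lognormal(0, 1.5, 100),
    ):
        rejections = 0
        reps = 2000
        for _ in range(reps):
            if route_and_compare(generator(), labels).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07


# --- screening and regression -------------------------------------------------

def test_exact_linear_relation_is_selected():
    df = pd.DataFrame({"age_yr": np.arange(30.0, 80.0), "y": 2 * np.arange(30.0, 80.0)})
    assert univariate_screen(df, "y", ["age_yr"]) == ["age_yr"]


def test_empty_candidate_set_selects_nothing():
    df = pd.DataFrame({"y": [1.0, 2.0, 3.0]})
    assert univariate_screen(df, "y", []) == []


def test_constant_candidate_excluded_with_warning():
    df = pd.DataFrame({"x": [1.0] * 20, "y": np.arange(20.0)})
    with pytest.warns(UserWarning):
        assert univariate_screen(df, "y", ["x"]) == []


def test_null_screen_selects_at_the_type_one_rate():
    rng = np.random.default_rng(7)
    n, n_cand, reps = 100, 10, 60
    total = 0
    for _ in range(reps):
        df = pd.DataFrame(rng.normal(size=(n, n_cand)), columns=[f"c{i}" for i in range(n_cand)])
        df["y"] = rng.normal(size=n)
        total += len(univariate_screen(df, "y", [f"c{i}" for i in range(n_cand)]))
    rate = total / (reps * n_cand)
    assert 0.02 <= rate <= 0.09


def test_regression_recovers_per_10ms_slope():
    rng = np.random.default_rng(3)
    t1 = rng.normal(1400, 60, 2000)
    df = pd.DataFrame({"aar_mean_t1_ms": t1, "y": 0.6 * t1 / 10 + rng.normal(0, 2, 2000)})
    res = multivariate_t1_model(df, "y", include_aar=False)
    assert res.beta == pytest.approx(0.6, abs=0.05)
    assert res.ci95[0] < 0.6 < res.ci95[1]
    assert res.scale == "per 10 ms"


def test_duplicated_covariates_raise_singular_error():
    rng = np.random.default_rng(4)
    df = pd.DataFrame({
        "aar_mean_t1_ms": rng.normal(1400, 60, 50),
        "a": rng.normal(size=50),
        "y": rng.normal(size=50),
    })
    df["b"] = df["a"]
    with pytest.raises(ValueError, match="collinear"):
        multivariate_t1_model(df, "y", ["a", "b"], include_aar=False)


def test_vif_flags_near_collinear_predictors():
    rng = np.random.default_rng(5)
    a = rng.normal(size=300)
    df = pd.DataFrame({
        "aar_mean_t1_ms": rng.normal(1400, 60, 300),
        "a": a,
        "b": a + rng.normal(0, 0.05, 300),
        "y": rng.normal(size=300),
    })
    res = multivariate_t1_model(df, "y", ["a", "b"], include_aar=False)
    assert set(res.collinearity_flags) >= {"a", "b"}


# --- ROC ---------------------------------------------------------------------

def test_perfect_separation_gives_auc_one():
    res = roc_analysis([1.0, 2.0, 3.0, 10.0, 11.0], [False, False, False, True, True])
    assert res.auc == 1.0
    assert res.sensitivity == 1.0 and res.specificity == 1.0
    assert res.optimal_threshold == 10.0


@pytest.mark.parametrize("seed", range(6))
def test_auc_equals_brute_force_pair_count(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 50))
    scores = rng.integers(0, 15, n).astype(float)  # integer scores force ties
    labels = rng.random(n) < 0.4
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    res = roc_analysis(scores, labels)
    assert res.auc == pytest.approx(ref.naive_auc(scores, labels), abs=1e-12)


def test_auc_matches_sklearn_reference():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(9)
    scores = rng.normal(size=80)
    labels = rng.random(80) < 0.5
    labels[0] = True
    labels[1] = False
    assert roc_analysis(scores, labels).auc == pytest.approx(
        roc_auc_score(labels, scores), abs=1e-12
    )


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(10)
    scores = rng.normal(1400, 50, 60)
    labels = rng.random(60) < 0.5
    labels[:2] = [True, False]
    base = roc_analysis(scores, labels)
    for f in (np.exp, lambda s: s**3, lambda s: 5 * s - 100):
        transformed = roc_analysis(f((scores - 1400) / 50), labels)
        assert transformed.auc == pytest.approx(base.auc, abs=1e-12)


def test_threshold_always_an_observed_score():
    rng = np.random.default_rng(11)
    scores = rng.normal(size=40)
    labels = rng.random(40) < 0.5
    labels[:2] = [True, False]
    res = roc_analysis(scores, labels)
    assert res.optimal_threshold in scores


def test_single_class_labels_rejected():
    with pytest.raises(ValueError):
        roc_analysis([1.0, 2.0], [True, True])


def test_diagnostic_metrics_hand_counted():
    m = diagnostic_metrics([1390.0, 1410.0, 1450.0], [False, True, True], 1400.0)
    assert m["sensitivity"] == 1.0
    assert m["specificity"] == 1.0
    assert m["ppv"] == 1.0 and m["npv"] == 1.0


def test_degenerate_denominators_reported_absent():
    m = diagnostic_metrics([1.0, 2.0], [True, False], 10.0)
    assert m["sensitivity"] == 0.0
    assert m["ppv"] is None


# --- model front end ----------------------------------------------------------

def test_cohort_analysis_end_to_end_summary():
    df = generate_cohort(CohortSimSpec(n_low=60, n_high=60, seed=12))
    results = CohortAnalysis(df).fit()
    assert results.regression.outcome == "final_infarct_pct"
    assert results.roc is not None
    assert 0.5 <= results.roc.auc <= 1.0
    text = results.summary()
    assert "ROC" in text and "beta" in text
    payload = results.to_dict()
    assert set(payload) >= {"regression", "comparisons", "roc"}
    # group comparison of the LGE column must use a recognised routed test
    assert results.comparisons["lge_pct_24h"].test_used in {"T_TEST", "MANN_WHITNEY"}
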