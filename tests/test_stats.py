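"""Welch tests, separation-safe logistic regression, best subset, ROC."""

from itertools import combinations

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from tuwave.stats import (
    GroupSummary,
    best_subset_logistic,
    fit_logistic,
    roc_analysis,
    welch_t,
    welch_t_summary,
)


def test_welch_from_summaries_matches_published_group_comparisons():
    """The printed group p values are reproduced from the summary stats."""
    _, df, p = welch_t_summary(GroupSummary(26.53, 12.33, 13, 10.39, 6.24, 13))
    assert p == pytest.approx(0.00054, abs=0.00001)
    _, _, p = welch_t_summary(GroupSummary(0.456, 0.261, 13, 0.767, 0.326, 13))
    assert p == pytest.approx(0.0132, abs=0.0002)
    _, _, p = welch_t_summary(GroupSummary(0.232, 0.018, 13, 0.165, 0.017, 13))
    assert p < 1e-4


def test_welch_equal_groups_give_t_zero_p_one():
    t, _, p = welch_t_summary(GroupSummary(1.0, 0.5, 10, 1.0, 0.5, 10))
    assert t == 0.0 and p == pytest.approx(1.0)


def test_welch_raw_data_consistent_with_summary_and_scipy():
    rng = np.random.default_rng(0)
    x1, x2 = rng.normal(0, 1, 20), rng.normal(0.5, 2, 15)
    t, df, p = welch_t(x1, x2)
    ref = sps.ttest_ind(x1, x2, equal_var=False)
    assert t == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)
    tp, _, pp = welch_t(x1, x2, equal_var=True)
    refp = sps.ttest_ind(x1, x2, equal_var=True)
    assert tp == pytest.approx(refp.statistic)
    assert pp == pytest.approx(refp.pvalue)


def test_welch_zero_sds_rejected():
    with pytest.raises(ValueError):
        welch_t_summary(GroupSummary(1.0, 0.0, 5, 2.0, 0.0, 5))


def _separated_data(rng):
    while True:
        a = rng.normal(0.232, 0.018, 13)
        c = rng.normal(0.165, 0.017, 13)
        if a.min() > c.max():
            x = np.concatenate([c, a])[:, None]
            y = np.r_[np.zeros(13), np.ones(13)]
            return x, y


def test_complete_separation_reports_aic_four():
    """One perfectly separating predictor: likelihood tends to 1, AIC to
    2 x 2 parameters = 4, and the separated flag is raised."""
    fit = fit_logistic(*_separated_data(np.random.default_rng(1)), names=["bue"])
    assert fit.separated
    assert round(fit.aic) == 4
    assert fit.log_likelihood >= -1e-6


def test_separated_coefficients_are_not_reproducible_but_aic_is():
    """Different separated datasets give the same limiting AIC while the
    coefficient values differ: under separation only the AIC (and the flag)
    are reproducible quantities."""
    fits = [fit_logistic(*_separated_data(np.random.default_rng(s)), names=["bue"])
            for s in (2, 3)]
    assert all(f.separated for f in fits)
    assert fits[0].aic == fits[1].aic == 4.0
    assert not np.allclose(fits[0].coefficients, fits[1].coefficients, rtol=0.05)


def test_logistic_matches_statsmodels_when_identified():
    rng = np.random.default_rng(4)
    x = rng.normal(size=(120, 3))
    p = 1 / (1 + np.exp(-(0.2 + x @ [0.8, -0.5, 0.0])))
    y = (rng.uniform(size=120) < p).astype(float)
    fit = fit_logistic(x, y)
    ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
    np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-5)
    assert fit.aic == pytest.approx(ref.aic, abs=1e-6)
    assert not fit.separated


def test_constant_predictor_rejected():
    y = np.r_[np.zeros(5), np.ones(5)]
    with pytest.raises(ValueError, match="constant predictor"):
        fit_logistic(np.ones((10, 1)), y)


def test_single_class_labels_rejected():
    with pytest.raises(ValueError, match="both classes"):
        fit_logistic(np.random.default_rng(0).normal(size=(8, 1)), np.ones(8))


def test_uninformative_predictor_loses_to_intercept_only():
    """With labels independent of the predictors, the intercept-only model
    has the lowest AIC (slopes cost 2 AIC each and buy ~nothing)."""
    rng = np.random.default_rng(5)
    x = rng.normal(size=(400, 2))
    y = rng.integers(0, 2, size=400).astype(float)
    best, _ = best_subset_logistic(x, y, ["a", "b"])
    assert best.predictor_subset == ()


def test_best_subset_is_exhaustive_and_matches_independent_enumeration():
    """The search fits exactly 2^k - 1 non-empty subsets and agrees with a
    brute-force enumeration done with statsmodels."""
    rng = np.random.default_rng(6)
    n, k = 60, 5
    x = rng.normal(size=(n, k))
    p = 1 / (1 + np.exp(-(0.3 + x @ [1.0, 0, 0, -0.7, 0])))
    y = (rng.uniform(size=n) < p).astype(float)
    names = ["p0", "p1", "p2", "p3", "p4"]
    best, n_fits = best_subset_logistic(x, y, names)
    assert n_fits == 2 ** k - 1

    oracle_best, oracle_aic = None, np.inf
    for r in range(1, k + 1):
        for combo in combinations(range(k), r):
            ref = sm.Logit(y, sm.add_constant(x[:, combo])).fit(disp=0)
            if ref.aic < oracle_aic - 1e-9:
                oracle_aic = ref.aic
                oracle_best = tuple(names[i] for i in combo)
    assert best.predictor_subset == oracle_best
    assert best.aic == pytest.approx(oracle_aic, abs=1e-5)


def test_best_subset_selects_the_separating_marker():
    """When exactly one predictor separates the groups, that single-variable
    model (AIC 4) wins over everything else."""
    rng = np.random.default_rng(7)
    x_sep, y = _separated_data(rng)
    x = np.column_stack([x_sep.ravel(), rng.normal(size=26), rng.normal(size=26)])
    best, _ = best_subset_logistic(x, y, ["bue", "noise1", "noise2"])
    assert best.predictor_subset == ("bue",)
    assert best.separated and round(best.aic) == 4


def test_roc_perfect_separation():
    rng = np.random.default_rng(8)
    x, y = _separated_data(rng)
    res = roc_analysis(x.ravel(), y.astype(bool))
    assert res.auc == 1.0
    assert res.sensitivity_counts == "13/13"
    assert res.specificity_counts == "13/13"
    # the Youden-optimal cutoff lies in the gap between the groups
    assert x.ravel()[y == 0].max() < res.cutoff <= x.ravel()[y == 1].min()


def test_roc_all_ties_gives_half():
    res = roc_analysis(np.ones(10), np.r_[np.ones(5), np.zeros(5)].astype(bool))
    assert res.auc == pytest.approx(0.5)


def test_roc_matches_brute_force_pairwise_statistic():
    values = np.array([0.1, 0.4, 0.35, 0.8])
    labels = np.array([False, True, False, True])
    res = roc_analysis(values, labels)
    pos, neg = values[labels], values[~labels]
    pairs = [(1.0 if p > q else 0.5 if p == q else 0.0)
             for p in pos for q in neg]
    assert res.auc == pytest.approx(np.mean(pairs))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(-10, 10).map(lambda v: round(v, 3)),
                min_size=6, max_size=20))
def test_roc_auc_invariant_under_monotone_transform(vals):
    values = np.asarray(vals)
    labels = np.arange(len(values)) % 2 == 0
    a = roc_analysis(values, labels).auc
    b = roc_analysis(np.exp(values / 5), labels).auc
    assert a == pytest.approx(b)


def test_roc_single_class_rejected():
    with pytest.raises(ValueError, match="both classes"):
        roc_analysis(np.arange(5.0), np.ones(5, dtype=bool))
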