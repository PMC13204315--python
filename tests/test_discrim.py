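"""Classifier, thresholds, ROC/PR, DeLong, calibration and rank comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from sklearn.metrics import roc_auc_score

from gliosig import discrim, syndata
from gliosig.discrim import (
    CalibrationReport,
    ClassifierConfig,
    ConfusionMetrics,
    calibration,
    choose_threshold,
    confusion_metrics,
    delong_auc_variance,
    delong_unpaired,
    fit_risk_model,
    label_permutation_test,
    learning_curve,
    rankscore_comparison,
    roc_pr,
    subgroup_auroc,
)

FAST_RF = ClassifierConfig(n_trees=40)


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------

def test_confusion_worked_example_from_holdout_counts():
    m = ConfusionMetrics(tp=42, fn=6, fp=9, tn=24)
    assert m.sensitivity == pytest.approx(0.875, abs=5e-4)
    assert m.specificity == pytest.approx(0.727, abs=5e-4)
    assert m.ppv == pytest.approx(0.824, abs=5e-4)
    assert m.npv == pytest.approx(0.800, abs=5e-4)
    assert m.accuracy == pytest.approx(0.815, abs=5e-4)
    # 84/99 = 0.8485, printed as 0.849 under half-up rounding
    assert m.f1 == pytest.approx(0.849, abs=1e-3)
    assert m.mcc == pytest.approx(0.613, abs=5e-4)
    assert m.balanced_accuracy == pytest.approx(0.801, abs=5e-4)


def test_confusion_all_correct_and_independent():
    perfect = ConfusionMetrics(tp=10, fn=0, fp=0, tn=10)
    assert perfect.mcc == 1.0 and perfect.f1 == 1.0 and perfect.accuracy == 1.0
    coin = ConfusionMetrics(tp=5, fn=5, fp=5, tn=5)
    assert coin.mcc == 0.0


@given(st.tuples(st.integers(0, 200), st.integers(0, 200),
                 st.integers(0, 200), st.integers(0, 200)))
def test_confusion_identities_hold_for_all_counts(counts):
    tp, fp, fn, tn = counts
    if tp + fp + fn + tn == 0:
        return
    m = ConfusionMetrics(tp=tp, fp=fp, fn=fn, tn=tn)
    if tp + fn:
        assert m.sensitivity == pytest.approx(tp / (tp + fn))
    if not math.isnan(m.mcc):
        assert -1 <= m.mcc <= 1
    if not math.isnan(m.balanced_accuracy):
        assert m.balanced_accuracy == pytest.approx((m.sensitivity + m.specificity) / 2)


def test_strict_threshold_rule_calls_ties_negative():
    m = confusion_metrics([1, 0], [0.5, 0.2], threshold=0.5)
    assert m.tp == 0 and m.fn == 1


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def test_train_median_threshold():
    choice = choose_threshold([0, 0, 1], [0.1, 0.2, 0.9], "train_median")
    assert choice.value == pytest.approx(0.2)


def test_optimising_strategies_separate_classes():
    scores = np.concatenate([np.linspace(0.0, 0.3, 30), np.linspace(0.7, 1.0, 30)])
    labels = np.array([0] * 30 + [1] * 30)
    for strategy in ("youden_j", "f1_max", "balanced_accuracy_max"):
        t = choose_threshold(labels, scores, strategy, folds=3, seed=0).value
        # fold-averaged optimum lies between the class score ranges
        assert 0.25 <= t < 0.7
        m = confusion_metrics(labels, scores, t)
        assert m.sensitivity + m.specificity - 1 == pytest.approx(1.0)


def test_unknown_strategy_rejected():
    with pytest.raises(ValueError):
        choose_threshold([0, 1], [0.1, 0.9], "magic")


# ---------------------------------------------------------------------------
# ROC / PR
# ---------------------------------------------------------------------------

def test_roc_pr_trivial_orderings():
    perfect = roc_pr([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
    assert perfect["auroc"] == 1.0 and perfect["auprc"] == 1.0
    constant = roc_pr([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
    assert constant["auroc"] == 0.5
    assert constant["baseline"] == 0.5
    with pytest.raises(ValueError):
        roc_pr([1, 1], [0.2, 0.4])


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_auroc_equals_normalised_mannwhitney_u(seed):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=60)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    s = rng.choice(np.linspace(0, 1, 25), size=60)   # ties included
    u = stats.mannwhitneyu(s[y == 1], s[y == 0]).statistic
    assert roc_pr(y, s)["auroc"] == pytest.approx(u / ((y == 1).sum() * (y == 0).sum()))


# ---------------------------------------------------------------------------
# risk model, learning curve, permutation
# ---------------------------------------------------------------------------

def test_model_is_deterministic_and_separates_planted_signal(planted_cohort):
    m = planted_cohort.expression.loc[planted_cohort.truth["informative_genes"]]
    a = fit_risk_model(m, planted_cohort.labels, FAST_RF)
    b = fit_risk_model(m, planted_cohort.labels, FAST_RF)
    np.testing.assert_allclose(a.train_scores, b.train_scores)
    assert roc_auc_score(planted_cohort.labels, a.train_scores) > 0.95


def test_model_requires_panel_genes(planted_cohort):
    m = planted_cohort.expression.iloc[:5]
    model = fit_risk_model(m, planted_cohort.labels, FAST_RF)
    with pytest.raises(KeyError):
        model.score(planted_cohort.expression.iloc[5:8])


def test_learning_curve_records_and_small_gap(planted_cohort):
    m = planted_cohort.expression.loc[planted_cohort.truth["informative_genes"]]
    lc = learning_curve(m, planted_cohort.labels, fractions=(0.5, 1.0), folds=3,
                        seed=0, config=FAST_RF)
    assert len(lc) == 2
    assert lc["gap"].iloc[-1] < 0.10


def test_permutation_test_bounds(planted_cohort, null_cohort):
    sig = planted_cohort.expression.loc[planted_cohort.truth["informative_genes"]]
    half = sig.shape[1] // 2
    res = label_permutation_test(
        sig.iloc[:, :half], planted_cohort.labels.iloc[:half],
        sig.iloc[:, half:], planted_cohort.labels.iloc[half:],
        n_perm=19, seed=0, config=FAST_RF)
    assert res["p_value"] == pytest.approx(1 / 20)
    assert abs(np.median(res["null_aurocs"]) - 0.5) < 0.15


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------

def test_delong_worked_example_and_perfect_separation():
    auc, var = delong_auc_variance([1, 1, 0, 0], [0.9, 0.6, 0.8, 0.5])
    assert auc == pytest.approx(0.75)
    assert var == pytest.approx(0.125)
    auc2, var2 = delong_auc_variance([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
    assert auc2 == 1.0 and var2 == 0.0


def test_delong_equal_degenerate_cohorts_give_p_one():
    res = delong_unpaired([1, 1, 0], [0.9, 0.8, 0.1], [1, 0, 0], [0.9, 0.2, 0.1])
    assert res.p == 1.0 and res.z == 0.0


def test_delong_variance_close_to_bootstrap():
    rng = np.random.default_rng(5)
    y = np.array([1] * 60 + [0] * 60)
    s = np.where(y == 1, rng.normal(0.8, 0.5, 120), rng.normal(0, 0.5, 120))
    _, var = delong_auc_variance(y, s)
    boots = []
    for _ in range(2000):
        idx = rng.integers(120, size=120)
        if len(np.unique(y[idx])) < 2:
            continue
        boots.append(roc_auc_score(y[idx], s[idx]))
    assert var == pytest.approx(np.var(boots, ddof=1), rel=0.15)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def test_calibration_trivial_and_baseline():
    y = np.array([0, 1] * 16)
    exact = calibration(y, y.astype(float), groups=8)
    assert exact.brier == 0.0 and exact.chi2 == 0.0
    p = 48 / 81
    assert p * (1 - p) == pytest.approx(0.241, abs=5e-4)


def test_calibrated_scores_give_plausible_chi2():
    rng = np.random.default_rng(2)
    s = rng.uniform(0.05, 0.95, size=800)
    y = (rng.random(800) < s).astype(int)
    rep = calibration(y, s, groups=8)
    assert rep.df == 6
    assert rep.p > 0.001
    assert rep.brier < rep.baseline
    assert rep.groups["n"].sum() == 800


def test_miscalibrated_scores_rejected():
    rng = np.random.default_rng(3)
    s = rng.uniform(0.4, 0.99, size=800)
    y = (rng.random(800) < 0.25).astype(int)   # systematic over-prediction
    rep = calibration(y, s, groups=8)
    assert rep.p < 0.001


# ---------------------------------------------------------------------------
# subgroup and rank comparisons
# ---------------------------------------------------------------------------

def test_subgroup_auroc_masks():
    y = [0, 1, 0, 1, 0, 1]
    s = [0.1, 0.9, 0.2, 0.8, 0.3, 0.7]
    assert subgroup_auroc(y, s, [True] * 6) == roc_pr(y, s)["auroc"]
    assert math.isnan(subgroup_auroc(y, s, [True, False] * 3))


def test_rankscore_u_identity():
    rng = np.random.default_rng(4)
    a, b = rng.normal(size=30), rng.normal(size=40)
    u_ab, _ = rankscore_comparison(a, b)
    u_ba, _ = rankscore_comparison(b, a)
    assert u_ab + u_ba == pytest.approx(30 * 40)
    _, p = rankscore_comparison(a - 3, b, alternative="less")
    assert p < 1e-6
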