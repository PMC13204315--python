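"""Risk classifier and the discrimination / calibration evaluation battery.

The risk model is a balanced random forest over z-score-normalised panel
expression; its posterior probability of the positive (GBM-like) class is the
continuous risk score used everywhere downstream.  The module also implements
the statistics of the validation battery: confusion metrics at an operating
threshold, four threshold-selection strategies, ROC/PR curves (trapezoidal
AUROC, step-integrated AUPRC), learning curves, label-permutation null tests,
the unpaired DeLong AUROC comparison from structural V10/V01 components,
Brier/Hosmer-Lemeshow calibration, subgroup AUROC and Mann-Whitney rank-score
comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .ingest import NormalizationReference, zscore_apply, zscore_fit

logger = logging.getLogger("gliosig")

__all__ = [
    "ClassifierConfig",
    "RiskModel",
    "ConfusionMetrics",
    "ThresholdChoice",
    "DeLongResult",
    "CalibrationReport",
    "fit_risk_model",
    "predict_scores",
    "confusion_metrics",
    "choose_threshold",
    "roc_pr",
    "learning_curve",
    "label_permutation_test",
    "delong_auc_variance",
    "delong_unpaired",
    "calibration",
    "subgroup_auroc",
    "rankscore_comparison",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Random-forest hyperparameters (balanced class weighting throughout)."""

    n_trees: int = 200
    max_depth: int = 10
    min_leaf: int = 3
    seed: int = 42

    def __post_init__(self):
        for name in ("n_trees", "max_depth", "min_leaf"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    def make_estimator(self) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_leaf,
            class_weight="balanced",
            random_state=self.seed,
        )


@dataclass
class RiskModel:
    estimator: RandomForestClassifier
    panel: list
    reference: NormalizationReference     # training-cohort normalisation
    train_scores: np.ndarray              # training score distribution
    config: ClassifierConfig

    def score(self, m: pd.DataFrame, reference: Optional[NormalizationReference] = None) -> pd.Series:
        """P(positive | x) for each sample (columns of ``m``).

        ``reference=None`` applies the stored training reference (the internal
        hold-out protocol); pass ``zscore_fit(m)`` for the per-cohort Method A
        external protocol, or a fixed deployment reference for Method B.  A
        pre-normalised matrix can be scored with ``reference="identity"``.
        """
        missing = [g for g in self.panel if g not in m.index]
        if missing:
            raise KeyError(
                f"panel genes missing from cohort (impute first): {missing}")
        sub = m.loc[self.panel]
        if reference == "identity":
            z = sub
        else:
            z = zscore_apply(sub, reference if reference is not None else self.reference)
        p = self.estimator.predict_proba(z.T.to_numpy())[:, 1]
        return pd.Series(p, index=m.columns, name="risk_score")


def fit_risk_model(
    train: pd.DataFrame,
    labels: pd.Series,
    config: ClassifierConfig = ClassifierConfig(),
) -> RiskModel:
    """Fit the balanced random forest on z-scored panel expression."""
    labels = pd.Series(labels).loc[train.columns].astype(int)
    if labels.nunique() != 2:
        raise ValueError("training requires both classes")
    ref = zscore_fit(train, source_cohort_id="train")
    z = zscore_apply(train, ref)
    est = config.make_estimator()
    est.fit(z.T.to_numpy(), labels.to_numpy())
    train_scores = est.predict_proba(z.T.to_numpy())[:, 1]
    return RiskModel(
        estimator=est, panel=list(train.index), reference=ref,
        train_scores=train_scores, config=config,
    )


def predict_scores(model: RiskModel, m: pd.DataFrame, reference=None) -> pd.Series:
    return model.score(m, reference=reference)


# ---------------------------------------------------------------------------
# confusion metrics and thresholds
# ---------------------------------------------------------------------------

def _safe_div(num: float, den: float) -> float:
    return num / den if den else float("nan")


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    ppv: float = field(init=False)
    npv: float = field(init=False)
    accuracy: float = field(init=False)
    f1: float = field(init=False)
    mcc: float = field(init=False)
    balanced_accuracy: float = field(init=False)

    def __post_init__(self):
        tp, fp, fn, tn = self.tp, self.fp, self.fn, self.tn
        self.sensitivity = _safe_div(tp, tp + fn)
        self.specificity = _safe_div(tn, tn + fp)
        self.ppv = _safe_div(tp, tp + fp)
        self.npv = _safe_div(tn, tn + fn)
        self.accuracy = _safe_div(tp + tn, tp + fp + fn + tn)
        self.f1 = _safe_div(2 * tp, 2 * tp + fp + fn)
        denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        self.mcc = _safe_div(tp * tn - fp * fn, denom)
        self.balanced_accuracy = (self.sensitivity + self.specificity) / 2


def confusion_metrics(labels, scores, threshold: float) -> ConfusionMetrics:
    """Counts and derived metrics with the strict rule predict positive iff score > threshold."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    pred = s > threshold
    return ConfusionMetrics(
        tp=int(((y == 1) & pred).sum()),
        fp=int(((y == 0) & pred).sum()),
        fn=int(((y == 1) & ~pred).sum()),
        tn=int(((y == 0) & ~pred).sum()),
    )


@dataclass(frozen=True)
class ThresholdChoice:
    strategy: str
    value: float
    folds: int = 0
    seed: Optional[int] = None


_CRITERIA = {
    "youden_j": lambda m: (m.sensitivity + m.specificity - 1),
    "f1_max": lambda m: m.f1,
    "balanced_accuracy_max": lambda m: m.balanced_accuracy,
}


def _best_threshold(y: np.ndarray, s: np.ndarray, criterion) -> float:
    """Candidate maximising the criterion, placed mid-way through its
    equivalence region (all t between two adjacent scores act identically
    under the strict score > t rule)."""
    uniq = np.unique(s)
    # a threshold strictly below the minimum makes everything positive
    candidates = np.concatenate(([uniq[0] - 1e-12], uniq))
    best_i, best_v = 0, -np.inf
    for i, t in enumerate(candidates):
        m = confusion_metrics(y, s, t)
        v = criterion(m)
        if np.isnan(v):
            continue
        if v > best_v:
            best_i, best_v = i, v
    t = candidates[best_i]
    upper = candidates[best_i + 1] if best_i + 1 < len(candidates) else t
    return float((t + upper) / 2)


def choose_threshold(
    train_labels,
    train_scores,
    strategy: str = "train_median",
    folds: int = 5,
    seed: Optional[int] = 42,
) -> ThresholdChoice:
    """Operating threshold from training scores.

    ``train_median`` is the median training risk score (the conservative rule
    used for survival dichotomisation); the three optimising strategies pick
    the fold-optimal threshold for Youden's J / F1 / balanced accuracy within
    stratified CV folds and average the fold optima.
    """
    y = np.asarray(train_labels, dtype=int)
    s = np.asarray(train_scores, dtype=float)
    if strategy == "train_median":
        return ThresholdChoice(strategy=strategy, value=float(np.median(s)), seed=seed)
    if strategy not in _CRITERIA:
        raise ValueError(f"unknown threshold strategy {strategy!r}")
    criterion = _CRITERIA[strategy]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_optima = [
        _best_threshold(y[fit_idx], s[fit_idx], criterion)
        for fit_idx, _ in skf.split(s.reshape(-1, 1), y)
    ]
    return ThresholdChoice(strategy=strategy, value=float(np.mean(fold_optima)),
                           folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# ROC / PR
# ---------------------------------------------------------------------------

def roc_pr(labels, scores) -> dict:
    """ROC and PR curves with trapezoidal AUROC and step-integrated AUPRC.

    The PR no-skill baseline is the positive prevalence.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("roc_pr requires both classes")
    fpr, tpr, _ = roc_curve(y, s)
    precision, recall, _ = precision_recall_curve(y, s)
    return {
        "fpr": fpr,
        "tpr": tpr,
        "auroc": float(roc_auc_score(y, s)),
        "precision": precision,
        "recall": recall,
        "auprc": float(average_precision_score(y, s)),
        "baseline": float(y.mean()),
    }


# ---------------------------------------------------------------------------
# learning curve and permutation null
# ---------------------------------------------------------------------------

def _cv_auroc(m: pd.DataFrame, labels: pd.Series, config: ClassifierConfig,
              folds: int, seed) -> np.ndarray:
    y = pd.Series(labels).loc[m.columns].astype(int).to_numpy()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for fit_idx, val_idx in skf.split(m.T.to_numpy(), y):
        cols_fit = m.columns[fit_idx]
        cols_val = m.columns[val_idx]
        model = fit_risk_model(m[cols_fit], pd.Series(y[fit_idx], index=cols_fit), config)
        s = model.score(m[cols_val])
        aucs.append(roc_auc_score(y[val_idx], s))
    return np.array(aucs)


def learning_curve(
    m: pd.DataFrame,
    labels: pd.Series,
    fractions: Sequence[float] = (0.1, 0.25, 0.5, 0.75, 1.0),
    folds: int = 5,
    seed: Optional[int] = 42,
    config: ClassifierConfig = ClassifierConfig(),
) -> pd.DataFrame:
    """Train vs CV AUROC at increasing training fractions; the last row's
    ``gap`` (train - CV) is the overfitting summary."""
    labels = pd.Series(labels).loc[m.columns].astype(int)
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        cols = []
        for cls in (0, 1):
            ids = list(m.columns[labels == cls])
            take = max(folds, int(round(frac * len(ids))))
            take = min(take, len(ids))
            cols.extend(np.array(ids, dtype=object)[rng.permutation(len(ids))[:take]])
        sub = m[cols]
        sub_y = labels.loc[cols]
        model = fit_risk_model(sub, sub_y, config)
        train_auc = roc_auc_score(sub_y, model.train_scores)
        cv = _cv_auroc(sub, sub_y, config, folds, seed)
        rows.append({
            "fraction": frac, "n": len(cols),
            "train_auroc": float(train_auc),
            "cv_auroc_mean": float(cv.mean()), "cv_auroc_sd": float(cv.std(ddof=1)),
            "gap": float(train_auc - cv.mean()),
        })
    return pd.DataFrame(rows)


def label_permutation_test(
    train: pd.DataFrame,
    train_labels: pd.Series,
    test: pd.DataFrame,
    test_labels: pd.Series,
    n_perm: int = 200,
    seed: Optional[int] = 42,
    config: ClassifierConfig = ClassifierConfig(),
) -> dict:
    """Null AUROC distribution from shuffled training labels.

    The full fit-and-score pipeline runs per permutation; the empirical p uses
    the add-one convention p = (#{null >= observed} + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    train_labels = pd.Series(train_labels).loc[train.columns].astype(int)
    test_labels = pd.Series(test_labels).loc[test.columns].astype(int)
    observed_model = fit_risk_model(train, train_labels, config)
    observed = roc_auc_score(test_labels, observed_model.score(test))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    y = train_labels.to_numpy()
    for i in range(n_perm):
        perm = pd.Series(rng.permutation(y), index=train.columns)
        model = fit_risk_model(train, perm, config)
        null[i] = roc_auc_score(test_labels, model.score(test))
    p = (float((null >= observed).sum()) + 1.0) / (n_perm + 1.0)
    return {"observed_auroc": float(observed), "null_aurocs": null, "p_value": p}


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------

@dataclass
class DeLongResult:
    auc_a: float
    var_a: float
    ci_a: tuple
    auc_b: float
    var_b: float
    ci_b: tuple
    z: float
    p: float


def _structural_components(labels, scores) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus per-positive (V10) and per-negative (V01) placement components."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes required")
    # psi(x, y) = 1 if x > y, 1/2 if tie, 0 otherwise
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return float(psi.mean()), v10, v01


def delong_auc_variance(labels, scores) -> tuple[float, float]:
    """Single-cohort AUC and its DeLong variance S10/m + S01/n."""
    auc, v10, v01 = _structural_components(labels, scores)
    s10 = v10.var(ddof=1) if v10.size > 1 else 0.0
    s01 = v01.var(ddof=1) if v01.size > 1 else 0.0
    return auc, float(s10 / v10.size + s01 / v01.size)


def delong_unpaired(labels_a, scores_a, labels_b, scores_b) -> DeLongResult:
    """Unpaired DeLong z-test for the AUROCs of two independent cohorts."""
    auc_a, var_a = delong_auc_variance(labels_a, scores_a)
    auc_b, var_b = delong_auc_variance(labels_b, scores_b)
    se = math.sqrt(var_a + var_b)
    if se == 0:
        z = 0.0 if auc_a == auc_b else math.copysign(math.inf, auc_a - auc_b)
    else:
        z = (auc_a - auc_b) / se
    p = 2 * stats.norm.sf(abs(z)) if math.isfinite(z) else 0.0
    half_a, half_b = 1.96 * math.sqrt(var_a), 1.96 * math.sqrt(var_b)
    return DeLongResult(
        auc_a=auc_a, var_a=var_a, ci_a=(auc_a - half_a, auc_a + half_a),
        auc_b=auc_b, var_b=var_b, ci_b=(auc_b - half_b, auc_b + half_b),
        z=float(z), p=float(p),
    )


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationReport:
    brier: float
    baseline: float          # no-information Brier p(1-p)
    chi2: float
    df: int
    p: float
    groups: pd.DataFrame     # per-group n, mean predicted, observed rate


def calibration(labels, scores, groups: int = 8) -> CalibrationReport:
    """Brier score and a Hosmer-Lemeshow chi-square over score-quantile groups.

    chi^2 = sum (O - E)^2 / (E (1 - E/n_g)) over groups, df = groups - 2;
    the no-information baseline is p(1-p) at the cohort prevalence.  Tied
    scores stay in one group; degenerate groups (zero expected variance) are
    skipped with the df reduced accordingly.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.size < groups:
        raise ValueError("need at least as many samples as groups")
    bins = pd.qcut(s, groups, duplicates="drop")
    frame = pd.DataFrame({"y": y, "s": s, "g": bins.codes})
    per = frame.groupby("g").agg(n=("y", "size"), observed=("y", "sum"),
                                 expected=("s", "sum"), mean_pred=("s", "mean"))
    per["observed_rate"] = per["observed"] / per["n"]
    chi2 = 0.0
    skipped = 0
    for _, row in per.iterrows():
        denom = row["expected"] * (1 - row["expected"] / row["n"])
        if denom <= 0:
            skipped += 1
            logger.info("calibration: group with zero expected variance skipped")
            continue
        chi2 += (row["observed"] - row["expected"]) ** 2 / denom
    df = len(per) - 2 - skipped
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    prevalence = y.mean()
    return CalibrationReport(
        brier=float(np.mean((s - y) ** 2)),
        baseline=float(prevalence * (1 - prevalence)),
        chi2=float(chi2), df=int(df), p=p,
        groups=per.reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# subgroup and rank-score comparisons
# ---------------------------------------------------------------------------

def subgroup_auroc(labels, scores, mask) -> float:
    """AUROC restricted to a boolean subgroup mask; NaN if single-class there."""
    y = np.asarray(labels, dtype=int)[np.asarray(mask, dtype=bool)]
    s = np.asarray(scores, dtype=float)[np.asarray(mask, dtype=bool)]
    if len(np.unique(y)) < 2:
        logger.info("subgroup_auroc: single-class subgroup, undefined")
        return float("nan")
    return float(roc_auc_score(y, s))


def rankscore_comparison(scores_a, scores_b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U (normal approximation, tie-corrected) between score groups."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return float(res.statistic), float(res.pvalue)
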