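"""ANOVA panel ranking, panel-size selection and signature-stability analyses.

Genes are ranked by the two-group one-way ANOVA F statistic (identical to the
squared pooled-variance t statistic); the panel size is chosen from a grid by
maximising mean cross-validated AUROC of the classifier on the top-N genes;
stability is quantified by bootstrap selection frequencies across nested pool
sizes, leave-one-gene-out retraining deltas, and pure-ANOVA baselines that
bypass the hypergraph/rough-set stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .discrim import ClassifierConfig, fit_risk_model

logger = logging.getLogger("gliosig")

__all__ = [
    "PanelSweepResult",
    "BootstrapStability",
    "anova_f",
    "sweep_panel_size",
    "bootstrap_selection_frequency",
    "leave_one_gene_out",
    "anova_baseline",
    "DEFAULT_SIZE_GRID",
]

DEFAULT_SIZE_GRID = (5, 8, 10, 12, 16, 20, 30, 50, 100)


def anova_f(m: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Per-gene two-group ANOVA F, descending (ties lexicographic by gene id).

    Zero within-group variance yields F = 0 at equal group means and an
    +inf sentinel (ranked first, logged) at unequal means.
    """
    labels = pd.Series(labels).loc[m.columns].astype(int)
    if (labels.value_counts() < 2).any() or labels.nunique() != 2:
        raise ValueError("both classes need >= 2 samples")
    x = m.to_numpy(dtype=float)
    y = labels.to_numpy()
    n = y.size
    x1, x0 = x[:, y == 1], x[:, y == 0]
    n1, n0 = x1.shape[1], x0.shape[1]
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    grand = x.mean(axis=1)
    ssb = n1 * (m1 - grand) ** 2 + n0 * (m0 - grand) ** 2
    ssw = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x0 - m0[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssb / (ssw / (n - 2))
    zero_ssw = ssw == 0
    f[zero_ssw & (ssb == 0)] = 0.0
    f[zero_ssw & (ssb > 0)] = np.inf
    if (zero_ssw & (ssb > 0)).any():
        logger.info("anova_f: %d genes with zero within-group variance ranked first",
                    int((zero_ssw & (ssb > 0)).sum()))
    s = pd.Series(f, index=m.index, name="F")
    order = sorted(s.index, key=lambda g: (-s[g], str(g)))
    return s.loc[order]


@dataclass
class PanelSweepResult:
    sizes: tuple
    cv_mean: pd.Series         # indexed by size
    cv_sd: pd.Series
    selected_size: int
    panel: list                # top genes at the selected size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cv_auroc_mean": self.cv_mean, "cv_auroc_sd": self.cv_sd})


def sweep_panel_size(
    m: pd.DataFrame,
    labels: pd.Series,
    candidate_pool: Sequence[str],
    sizes: Sequence[int] = DEFAULT_SIZE_GRID,
    folds: int = 5,
    seed: Optional[int] = 42,
    config: ClassifierConfig = ClassifierConfig(),
) -> PanelSweepResult:
    """CV AUROC of the classifier on the top-N ANOVA genes for each grid size N.

    The size attaining the maximum mean is selected (ties to the smallest N).
    The ANOVA ranking is recomputed inside each fold's fitting portion, so
    fold-validation performance is free of feature-selection leakage; the
    returned panel is the top-N of the full-training-partition ranking at the
    selected size.
    """
    pool = [g for g in candidate_pool if g in m.index]
    if max(sizes) > len(pool):
        raise ValueError(f"max size {max(sizes)} exceeds candidate pool {len(pool)}")
    labels = pd.Series(labels).loc[m.columns].astype(int)
    sub = m.loc[pool]
    ranking = anova_f(sub, labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(m.T.to_numpy(), labels.to_numpy()))
    aucs = {size: [] for size in sizes}
    for fit_idx, val_idx in splits:
        cols_fit, cols_val = m.columns[fit_idx], m.columns[val_idx]
        fold_ranking = anova_f(sub[cols_fit], labels.loc[cols_fit])
        for size in sizes:
            genes = list(fold_ranking.index[:size])
            model = fit_risk_model(m.loc[genes, cols_fit], labels.loc[cols_fit], config)
            aucs[size].append(
                roc_auc_score(labels.loc[cols_val], model.score(m.loc[genes, cols_val])))
    means = {size: float(np.mean(v)) for size, v in aucs.items()}
    sds = {size: float(np.std(v, ddof=1)) for size, v in aucs.items()}
    cv_mean = pd.Series(means)
    selected = int(min(s for s in sizes if cv_mean[s] == cv_mean.max()))
    return PanelSweepResult(
        sizes=tuple(sizes), cv_mean=cv_mean, cv_sd=pd.Series(sds),
        selected_size=selected, panel=list(ranking.index[:selected]),
    )


@dataclass
class BootstrapStability:
    frequencies: pd.DataFrame        # gene x pool size, in [0,1]
    n_boot: int
    variance_pool: int
    seed: Optional[int]
    signature_test: Optional[dict] = None   # one-sided rank-sum: signature > others


def bootstrap_selection_frequency(
    m: pd.DataFrame,
    labels: pd.Series,
    n_boot: int = 100,
    variance_pool: int = 5000,
    top_sizes: Sequence[int] = (50, 100, 200),
    seed: Optional[int] = 42,
    signature: Optional[Sequence[str]] = None,
) -> BootstrapStability:
    """Selection frequency of every gene inside the top-N ANOVA cut, over
    with-replacement resamples of the samples.

    Each iteration resamples columns, restricts to the ``variance_pool``
    highest-variance genes, ranks by F, and records membership of each cut.
    If a ``signature`` is given, its frequencies (largest cut) are compared
    against all other observed genes by a one-sided Mann-Whitney test.
    """
    labels = pd.Series(labels).loc[m.columns].astype(int)
    rng = np.random.default_rng(seed)
    top_sizes = sorted(top_sizes)
    counts = {k: {} for k in top_sizes}
    n = m.shape[1]
    for _ in range(n_boot):
        idx = rng.integers(n, size=n)
        while len(np.unique(labels.to_numpy()[idx])) < 2 or \
                min(np.bincount(labels.to_numpy()[idx], minlength=2)) < 2:
            idx = rng.integers(n, size=n)
        cols = m.columns[idx]
        boot = m[cols]
        boot.columns = [f"b{i}" for i in range(n)]
        boot_labels = pd.Series(labels.to_numpy()[idx], index=boot.columns)
        var = boot.var(axis=1, ddof=1)
        keep = var.sort_values(ascending=False).index[: min(variance_pool, len(var))]
        ranking = anova_f(boot.loc[keep], boot_labels)
        for k in top_sizes:
            for g in ranking.index[:k]:
                counts[k][g] = counts[k].get(g, 0) + 1
    genes = sorted(set().union(*[set(c) for c in counts.values()]))
    freq = pd.DataFrame(
        {k: [counts[k].get(g, 0) / n_boot for g in genes] for k in top_sizes},
        index=pd.Index(genes, name="gene_id"),
    )
    sig_test = None
    if signature is not None:
        sig = [g for g in signature if g in freq.index]
        others = freq.index.difference(sig)
        if sig and len(others):
            big = top_sizes[-1]
            res = stats.mannwhitneyu(freq.loc[sig, big], freq.loc[others, big],
                                     alternative="greater", method="asymptotic")
            sig_test = {"U": float(res.statistic), "p": float(res.pvalue),
                        "signature_median": float(freq.loc[sig, big].median()),
                        "other_median": float(freq.loc[others, big].median())}
    return BootstrapStability(frequencies=freq, n_boot=n_boot,
                              variance_pool=variance_pool, seed=seed,
                              signature_test=sig_test)


def leave_one_gene_out(
    panel: Sequence[str],
    train: tuple[pd.DataFrame, pd.Series],
    eval_sets: dict,
    survival_set: Optional[tuple] = None,
    config: ClassifierConfig = ClassifierConfig(),
) -> pd.DataFrame:
    """Retrain without each panel member; report AUROC deltas per evaluation
    set (and the class-adjusted risk-score hazard-ratio delta when a survival
    set ``(expression, survival_table)`` is supplied) relative to the full panel.
    """
    panel = list(panel)
    if len(panel) < 2:
        raise ValueError("leave-one-gene-out needs a panel of >= 2 genes")
    train_m, train_y = train

    def evaluate(genes):
        model = fit_risk_model(train_m.loc[genes], train_y, config)
        out = {}
        for name, (em, ey) in eval_sets.items():
            out[f"auroc_{name}"] = roc_auc_score(
                pd.Series(ey).loc[em.columns].astype(int), model.score(em))
        if survival_set is not None:
            from . import survmod
            sm, stab = survival_set
            scores = model.score(sm)
            tab = stab.copy()
            tab["risk_score"] = scores.loc[tab.index].to_numpy()
            fit = survmod.cox_fit(tab, ["risk_score", "is_positive_class"])
            out["hr_risk"] = float(fit.summary.loc["risk_score", "hazard_ratio"])
        return out

    full = evaluate(panel)
    rows = []
    for gene in panel:
        reduced = evaluate([g for g in panel if g != gene])
        row = {"omitted": gene}
        for key, value in full.items():
            row[f"delta_{key}"] = reduced[key] - value
        rows.append(row)
    return pd.DataFrame(rows).set_index("omitted")


def anova_baseline(
    m: pd.DataFrame,
    labels: pd.Series,
    sizes: Sequence[int] = (10, 15, 20, 30),
    folds: int = 5,
    seed: Optional[int] = 42,
    config: ClassifierConfig = ClassifierConfig(),
) -> pd.DataFrame:
    """Pure ANOVA top-N panels (no hypergraph / rough-set stages): CV AUROC per size."""
    if max(sizes) > m.shape[0]:
        raise ValueError(f"size {max(sizes)} exceeds gene count {m.shape[0]}")
    sweep = sweep_panel_size(m, labels, candidate_pool=list(m.index),
                             sizes=sizes, folds=folds, seed=seed, config=config)
    return sweep.to_frame()
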