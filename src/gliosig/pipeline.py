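"""End-to-end orchestration with frozen-parameter discipline.

Discovery runs entirely on the training partition: variance filter ->
co-expression hypergraph -> hyperdegree top-k candidates -> rough-set reduct
-> ANOVA ranking -> panel-size sweep -> risk-model fit -> operating threshold.
Every estimated quantity is recorded in a manifest together with the partition
it was estimated on; the held-out and external evaluations apply those frozen
parameters without refitting anything.

The ANOVA ranking pool is configurable: "hypergraph" (default — the top-k
hyperdegree candidates), "reduct" (only the rough-set reduct genes) or "all"
(every variance-filtered gene; the pure-ANOVA baseline path).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import discrim, hypernet, ingest, roughsel, sigpanel, survmod

logger = logging.getLogger("gliosig")

__all__ = [
    "PipelineConfig",
    "RunReport",
    "run_discovery",
    "run_internal_validation",
    "run_external_validation",
    "run_survival",
    "reduct_stability_analysis",
    "confound_transfer",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Stage parameters; the defaults are the reference operating point."""

    variance_threshold: float = 0.10
    variance_scope: str = "train_only"            # or "all" (leaky variant)
    tau: float = 0.75
    top_k_candidates: int = 300
    discretisation_bins: int = 3
    reduct_strategy: str = "greedy"               # greedy | stochastic | annealing
    annealing: roughsel.AnnealingSchedule = roughsel.AnnealingSchedule()
    anova_pool: str = "hypergraph"                # hypergraph | reduct | all
    size_grid: tuple = sigpanel.DEFAULT_SIZE_GRID
    cv_folds: int = 5
    classifier: discrim.ClassifierConfig = discrim.ClassifierConfig()
    threshold_strategy: str = "train_median"
    n_permutations: int = 200
    calibration_groups: int = 8
    survival_percentiles: tuple = (33, 50, 67)
    n_boot_selection: int = 100
    n_boot_optimism: int = 200
    split_fraction: float = 0.7
    seed: int = 42

    def stage_seed(self, offset: int) -> int:
        # fixed offsets so each stage is independently reproducible
        return (self.seed + 1000 * offset) % (2**31 - 1)


@dataclass
class RunReport:
    config: PipelineConfig
    split: ingest.CohortSplit
    filtered_genes: list
    hyperdegree: pd.Series
    candidates: list
    reduct: roughsel.Reduct
    cutpoints: pd.DataFrame
    sweep: sigpanel.PanelSweepResult
    panel: list
    model: discrim.RiskModel
    threshold: discrim.ThresholdChoice
    manifest: dict = field(default_factory=dict)

    def content_hash(self) -> str:
        payload = {
            "panel": self.panel,
            "threshold": round(self.threshold.value, 12),
            "reduct": sorted(map(str, self.reduct.attributes)),
            "gamma": round(self.reduct.gamma, 12),
            "selected_size": self.sweep.selected_size,
            "train_ids": list(map(str, self.split.train_ids)),
            "train_scores": [round(float(v), 12) for v in self.model.train_scores],
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _record(manifest: dict, name: str, partition: str, detail="") -> None:
    manifest[name] = {"estimated_on": partition, "detail": str(detail)}


def run_discovery(
    expression: pd.DataFrame,
    labels: pd.Series,
    config: PipelineConfig = PipelineConfig(),
) -> RunReport:
    """Discovery on the training partition only; returns the frozen artefacts."""
    ingest.validate_expression(expression)
    labels = pd.Series(labels).loc[expression.columns].astype(int)
    manifest: dict = {}

    split = ingest.stratified_split(labels, fraction=config.split_fraction, seed=config.seed)
    _record(manifest, "train_test_partition", "all (ids only)",
            f"train={len(split.train_ids)} test={len(split.test_ids)}")
    train = expression[list(split.train_ids)]
    train_labels = labels.loc[list(split.train_ids)]

    scope = train if config.variance_scope == "train_only" else expression
    kept = ingest.variance_filter(scope, config.variance_threshold).index
    train_f = train.loc[kept]
    _record(manifest, "variance_filter", f"{config.variance_scope} partition",
            f"{len(kept)} genes retained at {config.variance_threshold}")

    corr = hypernet.pairwise_pearson(train_f)
    hg = hypernet.build_hypergraph(corr, tau=config.tau)
    ranking = hypernet.hyperdegree(hg)
    candidates = hypernet.top_candidates(ranking, k=config.top_k_candidates)
    _record(manifest, "hypergraph", "train", f"tau={config.tau}, {len(candidates)} candidates")

    table = roughsel.discretise_equal_frequency(
        train_f.loc[candidates], train_labels, bins=config.discretisation_bins)
    _record(manifest, "discretisation_cutpoints", "train", "33rd/67th percentiles")
    if config.reduct_strategy == "greedy":
        reduct = roughsel.greedy_reduct(table)
    elif config.reduct_strategy == "stochastic":
        reduct = roughsel.stochastic_greedy_reduct(table, seed=config.stage_seed(3))
    elif config.reduct_strategy == "annealing":
        reduct = roughsel.simulated_annealing_reduct(table, config.annealing)
    else:
        raise ValueError(f"unknown reduct strategy {config.reduct_strategy!r}")
    _record(manifest, "reduct", "train",
            f"|R|={len(reduct.attributes)} gamma={reduct.gamma:.4f}")

    if config.anova_pool == "hypergraph":
        pool = candidates
    elif config.anova_pool == "reduct":
        pool = list(reduct.attributes)
    elif config.anova_pool == "all":
        pool = list(train_f.index)
    else:
        raise ValueError(f"unknown anova_pool {config.anova_pool!r}")
    sizes = tuple(s for s in config.size_grid if s <= len(pool)) or (len(pool),)
    sweep = sigpanel.sweep_panel_size(
        train_f, train_labels, candidate_pool=pool, sizes=sizes,
        folds=config.cv_folds, seed=config.seed, config=config.classifier)
    panel = sweep.panel
    _record(manifest, "panel", "train",
            f"size={sweep.selected_size} pool={config.anova_pool}")

    model = discrim.fit_risk_model(train.loc[panel], train_labels, config.classifier)
    _record(manifest, "normalisation_reference", "train", "per-gene mean/SD")
    _record(manifest, "classifier", "train", "balanced random forest")
    threshold = discrim.choose_threshold(
        train_labels.to_numpy(), model.train_scores,
        strategy=config.threshold_strategy, folds=config.cv_folds, seed=config.seed)
    _record(manifest, "operating_threshold", "train",
            f"{threshold.strategy}={threshold.value:.4f}")

    return RunReport(
        config=config, split=split, filtered_genes=list(kept),
        hyperdegree=ranking, candidates=candidates, reduct=reduct,
        cutpoints=table.cutpoints, sweep=sweep, panel=panel, model=model,
        threshold=threshold, manifest=manifest,
    )


def run_internal_validation(
    report: RunReport,
    expression: pd.DataFrame,
    labels: pd.Series,
) -> dict:
    """Evaluation battery on the locked test partition with frozen parameters."""
    test_ids = list(report.split.test_ids)
    test = expression.loc[report.panel, test_ids]
    y = pd.Series(labels).loc[test_ids].astype(int)
    scores = report.model.score(test)           # training normalisation reference
    curves = discrim.roc_pr(y, scores)
    cm = discrim.confusion_metrics(y, scores, report.threshold.value)
    cal = discrim.calibration(y, scores, groups=report.config.calibration_groups)
    report.manifest["internal_validation"] = {
        "estimated_on": "test (single access, frozen parameters)",
        "detail": f"n={len(test_ids)}",
    }
    return {"scores": scores, "labels": y, "roc_pr": curves,
            "confusion": cm, "calibration": cal}


def _normalise_external(m: pd.DataFrame, panel, method: str, reference=None) -> pd.DataFrame:
    present = [g for g in panel if g in m.index]
    missing = [g for g in panel if g not in m.index]
    sub = m.loc[present]
    if method == "A":
        z = ingest.zscore_apply(sub, ingest.zscore_fit(sub))
    elif method == "B":
        if reference is None:
            raise ValueError("Method B requires a fixed NormalizationReference")
        z = ingest.zscore_apply(sub, reference)
    elif method == "C":
        z = ingest.per_sample_rank_normalize(sub)
    else:
        raise ValueError(f"unknown normalisation method {method!r}")
    if missing:
        z = ingest.impute_missing_gene(z, missing)
    return z.loc[list(panel)]


def run_external_validation(
    report: RunReport,
    cohorts: dict,
    method: str = "A",
    reference: Optional[ingest.NormalizationReference] = None,
    internal: Optional[dict] = None,
    subgroup_masks: Optional[dict] = None,
) -> dict:
    """Score external cohorts without retraining (Method A/B/C normalisation).

    ``cohorts`` maps name -> (expression, labels).  Panel genes absent from a
    cohort are imputed at z = 0 (logged).  Returns per-cohort metrics plus the
    pairwise unpaired DeLong battery (including the internal hold-out when its
    results are supplied).
    """
    per_cohort: dict = {}
    for name, (m, labels) in cohorts.items():
        y = pd.Series(labels).loc[m.columns].astype(int)
        z = _normalise_external(m, report.panel, method, reference)
        scores = report.model.score(z, reference="identity")
        entry = {
            "scores": scores,
            "labels": y,
            "roc_pr": discrim.roc_pr(y, scores),
            "confusion": discrim.confusion_metrics(y, scores, report.threshold.value),
            "calibration": discrim.calibration(y, scores, report.config.calibration_groups),
            "imputed_genes": [g for g in report.panel if g not in m.index],
        }
        if subgroup_masks and name in subgroup_masks:
            entry["subgroup_auroc"] = {
                sg: discrim.subgroup_auroc(y, scores, mask)
                for sg, mask in subgroup_masks[name].items()
            }
        per_cohort[name] = entry
        report.manifest[f"external_validation_{name}"] = {
            "estimated_on": "external cohort (frozen parameters)",
            "detail": f"method {method}, n={m.shape[1]}",
        }
    battery = dict(per_cohort)
    if internal is not None:
        battery = {"internal_holdout": internal, **per_cohort}
    names = list(battery)
    delong = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            delong[(a, b)] = discrim.delong_unpaired(
                battery[a]["labels"], battery[a]["scores"],
                battery[b]["labels"], battery[b]["scores"])
    return {"cohorts": per_cohort, "delong": delong}


def run_survival(
    report: RunReport,
    expression: pd.DataFrame,
    survival_table: pd.DataFrame,
    method: str = "A",
    reference: Optional[ingest.NormalizationReference] = None,
) -> dict:
    """Survival battery on an external cohort with survival annotation.

    Scores the cohort with the frozen model, dichotomises at the configured
    training percentiles, and runs KM/log-rank, the multivariate Cox model,
    nested LRTs over predictor sets, and Harrell optimism correction.
    """
    if int(survival_table["event"].sum()) == 0:
        raise ValueError("survival cohort has zero events")
    z = _normalise_external(expression, report.panel, method, reference)
    scores = report.model.score(z, reference="identity")
    table = survival_table.copy()
    table["risk_score"] = scores.loc[table.index].to_numpy()

    km = {}
    for pct in report.config.survival_percentiles:
        high = survmod.dichotomise(table["risk_score"], report.model.train_scores, pct)
        if high.all() or not high.any():
            km[pct] = {"curves": None, "chi2": float("nan"), "p": float("nan"),
                       "note": "single risk group"}
            continue
        km[pct] = survmod.km_logrank(table, np.where(high, "high", "low"))

    covs = ["risk_score", "is_positive_class"]
    cox = survmod.cox_fit(table, covs)
    sets = {
        "class_only": ["is_positive_class"],
        "risk_only": ["risk_score"],
        "risk_plus_class": covs,
    }
    if "idh_wildtype" in table.columns and table["idh_wildtype"].nunique() == 2:
        sets["class_plus_idh"] = ["is_positive_class", "idh_wildtype"]
        sets["risk_class_idh"] = covs + ["idh_wildtype"]
    comparison = survmod.predictor_set_comparison(table, sets)
    optimism = survmod.harrell_optimism(
        table, covs, n_boot=report.config.n_boot_optimism,
        seed=report.config.stage_seed(7))
    report.manifest["survival"] = {
        "estimated_on": "external survival cohort (frozen model)",
        "detail": f"n={table.shape[0]}, events={int(table['event'].sum())}",
    }
    return {"table": table, "km_by_percentile": km, "cox": cox,
            "predictor_sets": comparison, "optimism": optimism}


# ---------------------------------------------------------------------------
# stability and confound analyses
# ---------------------------------------------------------------------------

def reduct_stability_analysis(
    table: roughsel.DecisionTable,
    objective,
    n_stochastic: int = 25,
    n_anneal: int = 5,
    schedule: roughsel.AnnealingSchedule = roughsel.AnnealingSchedule(),
    seed: int = 42,
) -> dict:
    """Alternative subsets from stochastic greedy + annealing, with Jaccard stats.

    ``objective`` maps an attribute list to the score the searches maximise
    (typically cross-validated AUROC of the subset).
    """
    subsets = []
    for i in range(n_stochastic):
        r = roughsel.stochastic_greedy_reduct(table, top_k=3, seed=seed + i)
        subsets.append(frozenset(r.attributes))
    for i in range(n_anneal):
        sched = roughsel.AnnealingSchedule(
            T0=schedule.T0, alpha=schedule.alpha, iterations=schedule.iterations,
            subset_size=min(schedule.subset_size, len(table.attributes)),
            seed=seed + 1000 + i)
        r = roughsel.simulated_annealing_reduct(table, sched, objective=objective)
        subsets.append(frozenset(r.attributes))
    pairwise = [
        roughsel.jaccard(subsets[i], subsets[j])
        for i in range(len(subsets)) for j in range(i + 1, len(subsets))
    ]
    scores = [objective(sorted(s, key=str)) for s in subsets]
    return {
        "subsets": subsets,
        "jaccard_mean": float(np.mean(pairwise)),
        "jaccard_median": float(np.median(pairwise)),
        "scores": np.asarray(scores),
    }


def confound_transfer(
    confounded,
    clean,
    panel_size: int = 10,
    config: discrim.ClassifierConfig = discrim.ClassifierConfig(),
    seed: int = 42,
) -> dict:
    """Train within a batch-confounded cohort; evaluate in-cohort and on a
    clean cohort from the same design.

    The signature is the ANOVA top-N of the confounded training split, so with
    zero biological signal the classifier can only learn the batch artefact:
    internal hold-out discrimination is inflated while transfer to the clean
    cohort collapses to chance.
    """
    split = ingest.stratified_split(confounded.labels, fraction=0.7, seed=seed)
    train_ids, test_ids = list(split.train_ids), list(split.test_ids)
    train = confounded.expression[train_ids]
    ranking = sigpanel.anova_f(train, confounded.labels.loc[train_ids])
    panel = list(ranking.index[:panel_size])
    model = discrim.fit_risk_model(train.loc[panel], confounded.labels.loc[train_ids], config)
    internal_scores = model.score(confounded.expression.loc[panel, test_ids])
    internal = discrim.roc_pr(confounded.labels.loc[test_ids], internal_scores)["auroc"]
    ext = _normalise_external(clean.expression, panel, method="A")
    transfer_scores = model.score(ext, reference="identity")
    transfer = discrim.roc_pr(clean.labels, transfer_scores)["auroc"]
    return {"panel": panel, "internal_auroc": float(internal),
            "transfer_auroc": float(transfer)}
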