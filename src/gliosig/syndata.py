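"""Synthetic two-class expression cohorts with planted structure.

The generator emulates the statistical features the analysis pipeline assumes
of a glioma grading cohort: a binary histology class (positive = GBM-like),
differentially expressed genes (mean-shift effect sizes in noise-SD units),
latent-factor co-expression modules with a tunable within-module Pearson
correlation, two platform scale profiles (microarray-like intensities vs
log2(RSEM+1)-like RNA-seq values), class-linked binary molecular covariates
(IDH-like, 1p/19q-codeletion-like), optional batch-class confounding, and
exponential survival times whose log-hazard depends on a risk covariate and
the class.

Module genes are generated as ``x = sqrt(rho) * f + sqrt(1 - rho) * eps`` with
a per-module shared latent factor ``f``, which gives pairwise within-module
correlation ``rho`` in expectation.  Planted informative genes are embedded in
the co-expression modules when modules exist (informative genes occupy the
leading gene slots, modules occupy the leading slots too), emulating the
disease-genes-within-coregulated-modules assumption that hypergraph hub
prioritisation relies on.

Class assignment is deterministic: exactly ``round(positive_fraction *
n_samples)`` positives, positions shuffled by the seeded generator, so
stratified-split arithmetic is exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticDesign",
    "SyntheticCohort",
    "SurvivalDesign",
    "generate_cohort",
    "generate_survival",
    "generate_confounded_pair",
    "write_cohort",
    "read_cohort",
]


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of a synthetic two-class cohort."""

    n_samples: int = 268
    positive_fraction: float = 159 / 268
    n_genes: int = 2000
    n_informative: int = 10
    effect_size: float = 1.5
    n_modules: int = 10
    module_size: int = 5
    module_rho: float = 0.8
    platform: str = "microarray_like"
    batch_confound: bool = False
    batch_offset: float = 2.0
    confound_fraction: float = 0.10
    idh_freq_positive: float = 0.05
    idh_freq_negative: float = 0.80
    codel_freq_positive: float = 0.02
    codel_freq_negative: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must lie in (0,1)")
        if self.n_informative > self.n_genes:
            raise ValueError(
                f"n_informative ({self.n_informative}) exceeds n_genes ({self.n_genes})")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError(
                f"n_modules*module_size ({self.n_modules * self.module_size}) "
                f"exceeds n_genes ({self.n_genes})")
        if not 0 <= self.module_rho < 1:
            raise ValueError("module_rho must lie in [0,1)")
        if self.platform not in ("microarray_like", "rnaseq_like"):
            raise ValueError(f"unknown platform {self.platform!r}")


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame          # genes x samples
    labels: pd.Series                 # 1 = positive (GBM-like), 0 = negative
    covariates: pd.DataFrame          # idh_like, codel_like per sample
    batch: Optional[pd.Series]        # batch id per sample, or None
    truth: dict                       # planted informative genes + module members
    design: SyntheticDesign


@dataclass(frozen=True)
class SurvivalDesign:
    """Exponential-hazard survival generator parameters (rates per day)."""

    baseline_rate: float = 1.0 / 1500.0
    beta_risk: float = 1.0
    beta_class: float = math.log(2.0)
    censor_rate: float = 1.0 / 4000.0
    max_follow_up: float = 5000.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("baseline_rate", "censor_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.max_follow_up <= 0:
            raise ValueError("max_follow_up must be positive")


def _gene_ids(n: int) -> pd.Index:
    width = max(4, len(str(n - 1)))
    return pd.Index([f"G{i:0{width}d}" for i in range(n)], name="gene_id")


def _sample_ids(n: int) -> pd.Index:
    width = max(4, len(str(n - 1)))
    return pd.Index([f"S{i:0{width}d}" for i in range(n)], name="sample_id")


def generate_cohort(design: SyntheticDesign) -> SyntheticCohort:
    """Draw one cohort; identical design + seed gives a bit-identical cohort."""
    design.validate()
    rng = np.random.default_rng(design.seed)
    n, g = design.n_samples, design.n_genes
    genes, samples = _gene_ids(g), _sample_ids(n)

    # deterministic class counts, positions shuffled
    n_pos = int(round(design.positive_fraction * n))
    y = np.zeros(n, dtype=int)
    y[rng.permutation(n)[:n_pos]] = 1

    x = rng.standard_normal((g, n))
    rho = design.module_rho
    module_members: dict[str, list[str]] = {}
    for m in range(design.n_modules):
        rows = slice(m * design.module_size, (m + 1) * design.module_size)
        f = rng.standard_normal(n)
        x[rows] = math.sqrt(rho) * f + math.sqrt(1.0 - rho) * x[rows]
        module_members[f"M{m}"] = list(genes[rows])

    informative = list(genes[: design.n_informative])
    if informative:
        x[: design.n_informative] += design.effect_size * y

    batch = None
    if design.batch_confound:
        # batch identity equals class; offset applied to a random gene subset
        batch = pd.Series(y, index=samples, name="batch")
        n_conf = max(1, int(round(design.confound_fraction * g)))
        conf_rows = rng.choice(g, size=n_conf, replace=False)
        x[conf_rows] += design.batch_offset * y
        confounded_genes = sorted(genes[conf_rows])
    else:
        confounded_genes = []

    if design.platform == "rnaseq_like":
        # pseudo-counts: exponentiate an intensity-like latent, then log2(x+1)
        x = np.log2(np.exp(x + 5.0) + 1.0)

    expr = pd.DataFrame(x, index=genes, columns=samples)

    idh_p = np.where(y == 1, design.idh_freq_positive, design.idh_freq_negative)
    codel_p = np.where(y == 1, design.codel_freq_positive, design.codel_freq_negative)
    covariates = pd.DataFrame(
        {
            "idh_like": (rng.random(n) < idh_p).astype(int),
            "codel_like": (rng.random(n) < codel_p).astype(int),
        },
        index=samples,
    )

    truth = {
        "informative_genes": informative,
        "modules": module_members,
        "confounded_genes": confounded_genes,
    }
    return SyntheticCohort(
        expression=expr,
        labels=pd.Series(y, index=samples, name="class"),
        covariates=covariates,
        batch=batch,
        truth=truth,
        design=design,
    )


def generate_confounded_pair(design: SyntheticDesign) -> SyntheticCohort:
    """Cohort in which batch identity equals the class label.

    With ``n_informative = 0`` the only class-separating signal is the batch
    artefact, so a classifier trained within the cohort learns batch identity;
    pair it with a clean ``generate_cohort`` draw of the same design (confound
    off, different seed) to demonstrate the transfer collapse.
    """
    if not design.batch_confound:
        raise ValueError("generate_confounded_pair requires batch_confound=True")
    return generate_cohort(design)


def generate_survival(
    cohort: SyntheticCohort,
    sdesign: SurvivalDesign,
    risk: np.ndarray | pd.Series,
) -> pd.DataFrame:
    """Exponential event times with log-hazard beta_risk*risk + beta_class*class.

    Censoring is the minimum of an independent exponential clock and the
    administrative follow-up horizon.  Returns a survival table with columns
    time_days, event, risk_score, is_positive_class (+ idh_wildtype).
    """
    sdesign.validate()
    risk = np.asarray(pd.Series(risk), dtype=float)
    n = cohort.labels.shape[0]
    if risk.shape[0] != n:
        raise ValueError(f"risk length {risk.shape[0]} != n_samples {n}")
    rng = np.random.default_rng(sdesign.seed)
    y = cohort.labels.to_numpy()
    rate = sdesign.baseline_rate * np.exp(sdesign.beta_risk * risk + sdesign.beta_class * y)
    t_event = rng.exponential(1.0 / np.where(rate > 0, rate, np.inf))
    if sdesign.censor_rate > 0:
        t_cens = rng.exponential(1.0 / sdesign.censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, sdesign.max_follow_up)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    return pd.DataFrame(
        {
            "time_days": np.maximum(time, 1e-8),
            "event": event.astype(int),
            "risk_score": risk,
            "is_positive_class": y,
            "idh_wildtype": 1 - cohort.covariates["idh_like"].to_numpy(),
        },
        index=cohort.labels.index,
    )


# ---------------------------------------------------------------------------
# round-trip I/O (TSV + truth JSON), matching the ingest readers
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, prefix, survival: Optional[pd.DataFrame] = None) -> None:
    from . import ingest

    prefix = str(prefix)
    ingest.write_expression(cohort.expression, prefix + ".expression.tsv")
    ann = pd.DataFrame({"sample_id": cohort.labels.index.astype(str)})
    ann["class"] = cohort.labels.to_numpy()
    ann["batch"] = (cohort.batch.to_numpy() if cohort.batch is not None else -1)
    ann["idh_like"] = cohort.covariates["idh_like"].to_numpy()
    ann["codel_like"] = cohort.covariates["codel_like"].to_numpy()
    if survival is not None:
        ann["time_days"] = survival["time_days"].to_numpy()
        ann["event"] = survival["event"].to_numpy()
    ingest.write_annotations(ann, prefix + ".annotations.tsv")
    with open(prefix + ".truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1)


def read_cohort(prefix) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    from . import ingest

    prefix = str(prefix)
    expr = ingest.read_expression(prefix + ".expression.tsv")
    ann = ingest.read_annotations(prefix + ".annotations.tsv")
    with open(prefix + ".truth.json") as fh:
        truth = json.load(fh)
    return expr, ann, truth
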