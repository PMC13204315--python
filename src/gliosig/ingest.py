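"""Expression/annotation I/O, label parsing, filtering, splitting and normalisation.

Expression matrices are plain :class:`pandas.DataFrame` objects with gene
identifiers as the row index and sample identifiers as columns — the universal
currency of every downstream stage.  Three normalisation protocols are
supported for applying a trained gene panel across platforms:

* **Method A** (per-cohort z-score): each gene standardised by the target
  cohort's own mean and SD (``zscore_fit`` + ``zscore_apply`` on the same
  cohort).
* **Method B** (fixed reference): a :class:`NormalizationReference` fitted once
  on a reference cohort is stored as a deployment artefact and applied to new
  cohorts or single samples.
* **Method C** (per-sample rank): within-sample ranks mapped to standard-normal
  quantiles; needs no reference distribution at all.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("gliosig")

__all__ = [
    "CohortSplit",
    "NormalizationReference",
    "read_expression",
    "write_expression",
    "read_annotations",
    "write_annotations",
    "validate_expression",
    "parse_grade_labels",
    "variance_filter",
    "stratified_split",
    "log2p1",
    "zscore_fit",
    "zscore_apply",
    "per_sample_rank_normalize",
    "impute_missing_gene",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSplit:
    """A stratified train/test partition of sample identifiers."""

    train_ids: tuple
    test_ids: tuple
    fraction: float
    seed: int

    def __post_init__(self):
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


@dataclass
class NormalizationReference:
    """Per-gene mean/SD lookup table (the Method B deployment artefact)."""

    mu: pd.Series
    sigma: pd.Series
    source_cohort_id: str = ""

    def __post_init__(self):
        if not self.mu.index.equals(self.sigma.index):
            raise ValueError("mu and sigma must share one gene index")
        if (self.sigma < 0).any():
            raise ValueError("negative standard deviation in reference")

    @property
    def gene_ids(self) -> pd.Index:
        return self.mu.index

    def to_json(self, path) -> None:
        payload = {
            "source_cohort_id": self.source_cohort_id,
            "genes": {
                g: [float(self.mu[g]), float(self.sigma[g])] for g in self.mu.index
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NormalizationReference":
        with open(path) as fh:
            payload = json.load(fh)
        genes = payload["genes"]
        idx = pd.Index(list(genes), name="gene_id")
        mu = pd.Series([genes[g][0] for g in idx], index=idx, dtype=float)
        sigma = pd.Series([genes[g][1] for g in idx], index=idx, dtype=float)
        return cls(mu=mu, sigma=sigma, source_cohort_id=payload.get("source_cohort_id", ""))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def validate_expression(m: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix contract (unique ids, finite values)."""
    if m.index.has_duplicates:
        raise ValueError("duplicate gene identifiers")
    if m.columns.has_duplicates:
        raise ValueError("duplicate sample identifiers")
    values = m.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite expression values; impute before use")
    return m


def read_expression(path, sep: str = "\t") -> pd.DataFrame:
    m = pd.read_csv(path, sep=sep, index_col=0)
    m.index = m.index.astype(str)
    m.index.name = "gene_id"
    m.columns = m.columns.astype(str)
    return validate_expression(m.astype(float))


def write_expression(m: pd.DataFrame, path, sep: str = "\t") -> None:
    validate_expression(m)
    out = m.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep=sep, float_format="%.10g")


def read_annotations(path, sep: str = "\t") -> pd.DataFrame:
    ann = pd.read_csv(path, sep=sep)
    if "sample_id" not in ann.columns:
        raise ValueError("annotation table requires a sample_id column")
    ann["sample_id"] = ann["sample_id"].astype(str)
    if "time_days" in ann.columns and "event" not in ann.columns:
        raise ValueError("time_days present without an event flag")
    return ann


def write_annotations(ann: pd.DataFrame, path, sep: str = "\t") -> None:
    ann.to_csv(path, sep=sep, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# label parsing
# ---------------------------------------------------------------------------

# "grade IV" also as the upper end of a range such as "grade II-IV"
_POSITIVE_RE = re.compile(r"grade\s*(?:i{1,3}\s*[-–/]\s*)?iv|gbm", re.IGNORECASE)
_NEGATIVE_RE = re.compile(r"grade\s*ii(?!i)|grade\s*iii", re.IGNORECASE)


def parse_grade_labels(raw: Sequence[str]) -> pd.Series:
    """Map free-text histology strings to positive/negative/excluded.

    "grade IV" or "GBM" (case-insensitive substring) marks the positive
    (grade-IV) class; "grade II" or "grade III" marks the negative class.
    The positive pattern takes precedence when both occur (e.g. "grade
    II-IV"); anything else is excluded and logged.
    """
    out = []
    for s in raw:
        text = str(s)
        if _POSITIVE_RE.search(text):
            out.append("positive")
        elif _NEGATIVE_RE.search(text):
            out.append("negative")
        else:
            logger.info("histology string excluded: %r", text)
            out.append("excluded")
    index = raw.index if isinstance(raw, (pd.Series, pd.Index)) else pd.RangeIndex(len(out))
    return pd.Series(out, index=index)


# ---------------------------------------------------------------------------
# filtering / splitting / transforms
# ---------------------------------------------------------------------------

def variance_filter(m: pd.DataFrame, threshold: float = 0.10) -> pd.DataFrame:
    """Drop genes whose sample variance (n-1 denominator) falls below ``threshold``."""
    if m.shape[1] < 2:
        raise ValueError("variance filter requires at least 2 samples")
    var = m.var(axis=1, ddof=1)
    kept = m.loc[var >= threshold]
    logger.info("variance_filter: %d of %d genes retained (threshold %.3g)",
                kept.shape[0], m.shape[0], threshold)
    if kept.empty:
        logger.warning("variance_filter removed every gene")
    return kept


def stratified_split(labels: pd.Series, fraction: float = 0.7, seed: int = 42) -> CohortSplit:
    """Seeded per-class split: floor(fraction x class size) to train, rest to test."""
    labels = pd.Series(labels)
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"stratified_split requires exactly two classes, got {list(classes)}")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in sorted(map(str, classes)):
        ids = sorted(labels.index[labels.astype(str) == cls], key=str)
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        ids = list(np.array(ids, dtype=object)[rng.permutation(len(ids))])
        n_train = int(np.floor(fraction * len(ids)))
        train.extend(ids[:n_train])
        test.extend(ids[n_train:])
    return CohortSplit(train_ids=tuple(train), test_ids=tuple(test),
                       fraction=fraction, seed=seed)


def log2p1(m: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(x+1); rejects negative input."""
    if (m.to_numpy() < 0).any():
        raise ValueError("log2p1 requires non-negative values")
    return np.log2(m + 1.0)


def zscore_fit(m: pd.DataFrame, source_cohort_id: str = "") -> NormalizationReference:
    """Fit per-gene mean and sample SD (n-1) on a cohort."""
    return NormalizationReference(
        mu=m.mean(axis=1),
        sigma=m.std(axis=1, ddof=1).fillna(0.0),
        source_cohort_id=source_cohort_id,
    )


def zscore_apply(m: pd.DataFrame, ref: NormalizationReference) -> pd.DataFrame:
    """z = (x - mu_j) / sigma_j with mu, sigma taken from ``ref``.

    Genes with sigma = 0 map to z = 0 (the z-score-zero imputation
    convention for uninformative features), with a warning.
    """
    missing = m.index.difference(ref.gene_ids)
    if len(missing):
        raise KeyError(f"genes absent from reference: {list(missing)[:5]}")
    mu = ref.mu.loc[m.index]
    sigma = ref.sigma.loc[m.index]
    degenerate = sigma == 0
    if degenerate.any():
        logger.warning("zscore_apply: %d zero-SD genes set to z=0", int(degenerate.sum()))
    safe = sigma.replace(0.0, 1.0)
    z = m.sub(mu, axis=0).div(safe, axis=0)
    z.loc[degenerate] = 0.0
    return z


def per_sample_rank_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Method C: within-sample average ranks mapped to Phi^-1((r-0.5)/m)."""
    from scipy.stats import norm

    if m.shape[0] < 2:
        raise ValueError("rank normalisation requires >= 2 genes per sample")
    ranks = m.rank(axis=0, method="average")
    return pd.DataFrame(
        norm.ppf((ranks - 0.5) / m.shape[0]),
        index=m.index, columns=m.columns,
    )


def impute_missing_gene(m: pd.DataFrame, genes: Iterable[str]) -> pd.DataFrame:
    """Append all-zero rows for panel genes missing from a z-scored cohort.

    A zero z-score equals the cohort mean; the imputation is logged so the
    evaluation report can record it.
    """
    genes = list(genes)
    already = [g for g in genes if g in m.index]
    if already:
        raise ValueError(f"genes already present: {already}")
    if not genes:
        return m
    logger.info("impute_missing_gene: imputing %s as z=0", genes)
    zeros = pd.DataFrame(0.0, index=pd.Index(genes, name=m.index.name), columns=m.columns)
    return pd.concat([m, zeros])
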