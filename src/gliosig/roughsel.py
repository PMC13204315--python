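"""Rough-set attribute reduction over discretised expression tables.

The training cohort is formalised as a decision information system: objects
(samples) x conditional attributes (genes discretised into low/medium/high by
equal-frequency binning) with a binary decision (class label).  For an
attribute subset B, the *positive region* POS_B(D) is the union of
indiscernibility classes that are pure in the decision, and the *dependency
degree* gamma_B(D) = |POS_B(D)| / |U| is the fraction of objects whose class
is deterministically inferable from B.  A *reduct* is a minimal subset R with
gamma_R = gamma_A.

Three searches are provided: deterministic forward greedy (argmax incremental
gamma gain, lexicographic tie-break, additions continue until gamma_R reaches
gamma_A, then a backward pruning pass restores minimality), a stochastic
greedy variant (each addition drawn uniformly from the top-k candidates by
gain), and simulated annealing over fixed-size subsets under a geometric
cooling schedule.  An exhaustive enumeration oracle supports testing on small
tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("gliosig")

__all__ = [
    "DecisionTable",
    "Reduct",
    "AnnealingSchedule",
    "discretise_equal_frequency",
    "indiscernibility_classes",
    "dependency_degree",
    "greedy_reduct",
    "stochastic_greedy_reduct",
    "simulated_annealing_reduct",
    "jaccard",
    "exhaustive_reduct_oracle",
]


@dataclass
class DecisionTable:
    """Objects x categorical attributes plus a binary decision."""

    objects: list                      # sample ids
    attributes: list                   # gene ids
    values: np.ndarray                 # int codes, n_objects x n_attributes
    decision: np.ndarray               # 0/1 per object
    cutpoints: Optional[pd.DataFrame] = None   # per-attribute [c1, c2]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.decision = np.asarray(self.decision)
        if self.values.shape != (len(self.objects), len(self.attributes)):
            raise ValueError("values shape inconsistent with object/attribute lists")
        if self.decision.shape[0] != len(self.objects):
            raise ValueError("decision length inconsistent with objects")

    def attribute_index(self, attrs: Iterable) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.attributes)}
        try:
            return np.array([pos[a] for a in attrs], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown attribute {exc.args[0]!r}") from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.objects, columns=self.attributes)
        df["decision"] = self.decision
        return df


@dataclass
class Reduct:
    attributes: list
    gamma: float
    gamma_full: float
    search_trace: list = field(default_factory=list)   # (attribute, gain) in order added


@dataclass(frozen=True)
class AnnealingSchedule:
    """Geometric cooling: T_k = T0 * alpha^k."""

    T0: float = 0.05
    alpha: float = 0.95
    iterations: int = 80
    subset_size: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        if self.T0 <= 0:
            raise ValueError("T0 must be positive")

    def temperature(self, k: int) -> float:
        return self.T0 * self.alpha ** k


# ---------------------------------------------------------------------------
# discretisation
# ---------------------------------------------------------------------------

def discretise_equal_frequency(
    m: pd.DataFrame,
    labels: pd.Series,
    bins: int = 3,
    cutpoints: Optional[pd.DataFrame] = None,
) -> DecisionTable:
    """Equal-frequency binning of a genes x samples matrix into a decision table.

    Cut-points sit at the 33.33rd/66.67th percentiles of the supplied values
    (generally the training cohort); pass a previously fitted ``cutpoints``
    frame to apply frozen training cut-points to new samples.  Binning uses
    half-open intervals (-inf, c1], (c1, c2], (c2, inf): ties at a cut-point
    fall to the lower bin.  Degenerate genes collapse to fewer effective bins.
    """
    if bins != 3:
        raise ValueError("three bins (low/medium/high) are the supported scheme")
    labels = pd.Series(labels).loc[m.columns]
    x = m.to_numpy(dtype=float)
    if cutpoints is None:
        c = np.quantile(x, [1 / 3, 2 / 3], axis=1).T    # n_genes x 2
        cutpoints = pd.DataFrame(c, index=m.index, columns=["c1", "c2"])
        degenerate = cutpoints["c1"] == cutpoints["c2"]
        if degenerate.any():
            logger.info("discretise: %d genes with coincident cut-points", int(degenerate.sum()))
    else:
        cutpoints = cutpoints.loc[m.index]
    c1 = cutpoints["c1"].to_numpy()[:, None]
    c2 = cutpoints["c2"].to_numpy()[:, None]
    codes = (x > c1).astype(np.int8) + (x > c2).astype(np.int8)
    return DecisionTable(
        objects=list(m.columns),
        attributes=list(m.index),
        values=codes.T,
        decision=labels.to_numpy().astype(int),
        cutpoints=cutpoints,
    )


# ---------------------------------------------------------------------------
# indiscernibility and dependency
# ---------------------------------------------------------------------------

def _group_ids(values: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Integer indiscernibility-class id per object under the given columns."""
    n = values.shape[0]
    if cols.size == 0:
        return np.zeros(n, dtype=np.int64)
    _, inv = np.unique(values[:, cols], axis=0, return_inverse=True)
    return inv


def indiscernibility_classes(t: DecisionTable, B: Iterable) -> list:
    """Partition of the objects by identical value tuples on B (B=empty -> one class)."""
    cols = t.attribute_index(B)
    inv = _group_ids(t.values, cols)
    out: dict[int, list] = {}
    for obj, gid in zip(t.objects, inv):
        out.setdefault(int(gid), []).append(obj)
    return [out[k] for k in sorted(out)]


def _gamma_from_groups(inv: np.ndarray, decision: np.ndarray) -> float:
    n_groups = int(inv.max()) + 1 if inv.size else 0
    sizes = np.bincount(inv, minlength=n_groups)
    positives = np.bincount(inv, weights=decision, minlength=n_groups)
    pure = (positives == 0) | (positives == sizes)
    return float(sizes[pure].sum() / decision.shape[0])


def dependency_degree(t: DecisionTable, B: Iterable) -> float:
    """gamma_B(D): fraction of objects in decision-pure indiscernibility classes."""
    cols = t.attribute_index(B)
    return _gamma_from_groups(_group_ids(t.values, cols), t.decision)


# ---------------------------------------------------------------------------
# reduct searches
# ---------------------------------------------------------------------------

def _refine(inv: np.ndarray, col_values: np.ndarray) -> np.ndarray:
    """Refine a partition id vector by one extra attribute column."""
    # dense re-encoding keeps keys small across many iterations
    n_codes = int(col_values.max()) + 1 if col_values.size else 1
    key = inv.astype(np.int64) * n_codes + col_values
    _, new_inv = np.unique(key, return_inverse=True)
    return new_inv


def _prune(t: DecisionTable, selected: list, target: float) -> list:
    """Backward pass: drop any attribute whose removal keeps gamma at target.

    One sequential pass suffices for superset-minimality: gamma is monotone in
    the attribute set, so an attribute whose removal lowered gamma against a
    superset also lowers it against any subset kept later.
    """
    kept = list(selected)
    for a in list(selected):
        trial = [b for b in kept if b != a]
        if dependency_degree(t, trial) >= target:
            kept = trial
    return kept


def _forward_selection(
    t: DecisionTable,
    pick: Callable[[list], object],
) -> Reduct:
    """Shared forward loop: ``pick`` chooses among (gain, attribute) candidates."""
    gamma_full = dependency_degree(t, t.attributes)
    n = len(t.objects)
    inv = np.zeros(n, dtype=np.int64)
    current_gamma = _gamma_from_groups(inv, t.decision)
    selected: list = []
    trace: list = []
    remaining = sorted(t.attributes, key=str)
    col_of = {a: i for i, a in enumerate(t.attributes)}
    while current_gamma < gamma_full and remaining:
        candidates = []
        for a in remaining:
            trial_inv = _refine(inv, t.values[:, col_of[a]])
            g = _gamma_from_groups(trial_inv, t.decision)
            candidates.append((g - current_gamma, a, trial_inv, g))
        chosen = pick(candidates)
        gain, a, inv, current_gamma = chosen[0], chosen[1], chosen[2], chosen[3]
        selected.append(a)
        trace.append((a, float(gain)))
        remaining.remove(a)
    kept = _prune(t, selected, current_gamma)
    return Reduct(
        attributes=kept,
        gamma=dependency_degree(t, kept),
        gamma_full=gamma_full,
        search_trace=trace,
    )


def greedy_reduct(t: DecisionTable) -> Reduct:
    """Forward greedy (Eq.-4-style argmax incremental gain) plus backward pruning.

    Additions continue until gamma_R reaches gamma_A — zero-gain plateaus
    (attribute interactions) are crossed by taking the lexicographically first
    argmax — and the pruning pass then removes every attribute whose deletion
    leaves gamma unchanged, making the output superset-minimal.
    """
    def pick(cands):
        return max(cands, key=lambda c: (c[0], _NegStr(c[1])))

    return _forward_selection(t, pick)


class _NegStr:
    """Orders strings descending so max() breaks gain ties lexicographically ascending."""

    __slots__ = ("s",)

    def __init__(self, s):
        self.s = str(s)

    def __lt__(self, other):
        return self.s > other.s

    def __eq__(self, other):
        return self.s == other.s


def stochastic_greedy_reduct(t: DecisionTable, top_k: int = 3, seed: Optional[int] = None) -> Reduct:
    """As greedy, but each addition is drawn uniformly from the top-k gains."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    rng = np.random.default_rng(seed)

    def pick(cands):
        ranked = sorted(cands, key=lambda c: (-c[0], str(c[1])))
        pool = ranked[: min(top_k, len(ranked))]
        return pool[rng.integers(len(pool))]

    return _forward_selection(t, pick)


def simulated_annealing_reduct(
    t: DecisionTable,
    schedule: AnnealingSchedule = AnnealingSchedule(),
    objective: Optional[Callable[[Sequence], float]] = None,
) -> Reduct:
    """Fixed-size subset search by single-gene swaps under geometric cooling.

    ``objective`` maps an attribute list to a score to maximise; the default is
    the dependency degree gamma.  A proposal with non-negative improvement is
    always accepted; a worsening of Delta is accepted with probability
    exp(-Delta / T_k), T_k = T0 * alpha^k.
    """
    if schedule.subset_size > len(t.attributes):
        raise ValueError("subset_size exceeds the number of attributes")
    if objective is None:
        objective = lambda attrs: dependency_degree(t, attrs)
    rng = np.random.default_rng(schedule.seed)
    attrs = sorted(t.attributes, key=str)
    current = list(rng.choice(len(attrs), size=schedule.subset_size, replace=False))
    current_set = [attrs[i] for i in sorted(current)]
    current_score = objective(current_set)
    best_set, best_score = list(current_set), current_score
    trace = [("init", float(current_score))]
    for k in range(schedule.iterations):
        inside = rng.integers(len(current_set))
        outside_pool = [a for a in attrs if a not in current_set]
        if not outside_pool:
            break
        swap_in = outside_pool[rng.integers(len(outside_pool))]
        proposal = list(current_set)
        proposal[inside] = swap_in
        proposal.sort(key=str)
        score = objective(proposal)
        delta = current_score - score          # positive = worse
        if delta <= 0 or rng.random() < math.exp(-delta / schedule.temperature(k)):
            current_set, current_score = proposal, score
            trace.append((swap_in, float(score)))
            if score > best_score:
                best_set, best_score = list(proposal), score
    return Reduct(
        attributes=best_set,
        gamma=dependency_degree(t, best_set),
        gamma_full=dependency_degree(t, t.attributes),
        search_trace=trace,
    )


def jaccard(a: Iterable, b: Iterable) -> float:
    """|A n B| / |A u B|; two empty sets are defined as identical (1, logged)."""
    a, b = set(a), set(b)
    if not a and not b:
        logger.info("jaccard of two empty sets defined as 1")
        return 1.0
    return len(a & b) / len(a | b)


def exhaustive_reduct_oracle(t: DecisionTable, max_attributes: int = 15) -> list:
    """All minimal attribute subsets achieving gamma_A, by exact enumeration."""
    from itertools import combinations

    attrs = list(t.attributes)
    if len(attrs) > max_attributes:
        raise ValueError(f"{len(attrs)} attributes exceed the oracle cap {max_attributes}")
    gamma_full = dependency_degree(t, attrs)
    minimal: list = []
    for size in range(0, len(attrs) + 1):
        for subset in combinations(attrs, size):
            ss = set(subset)
            if any(found <= ss for found in minimal):
                continue
            if dependency_degree(t, subset) >= gamma_full:
                minimal.append(frozenset(subset))
    return minimal
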