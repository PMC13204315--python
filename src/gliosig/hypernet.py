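"""Weighted co-expression hypergraphs and hyperdegree gene prioritisation.

For every gene g_i an *ego hyperedge* e_i is built containing g_i plus all
genes g_j with |r_ij| > tau (Pearson, both signs of co-expression count).  The
hyperedge weight aggregates the co-expression strength of its members; the
default ("seed_anchored") sums |r(seed, member)| over non-seed members, the
"all_pairs" alternative sums |r| over every unordered member pair.  The
hyperdegree of a gene is the sum of the weights of all hyperedges containing
it, and genes are ranked by descending hyperdegree (ties broken
lexicographically by gene id).

A permutation null — every gene's sample vector independently shuffled —
quantifies how many suprathreshold pairs sampling noise alone produces on a
tau grid, yielding an empirical FDR for the hyperedge threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("gliosig")

__all__ = [
    "Hyperedge",
    "CoexpressionHypergraph",
    "ThresholdNullResult",
    "pairwise_pearson",
    "build_hypergraph",
    "hyperdegree",
    "top_candidates",
    "permutation_edge_null",
    "DEFAULT_TAU_GRID",
]

DEFAULT_TAU_GRID = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


class Hyperedge(NamedTuple):
    seed: str
    members: frozenset
    weight: float


@dataclass
class CoexpressionHypergraph:
    vertices: list
    hyperedges: list          # one Hyperedge per vertex, same order
    tau: float

    def to_json_dict(self) -> dict:
        return {
            "tau": self.tau,
            "hyperedges": [
                {"seed": e.seed, "members": sorted(e.members), "weight": e.weight}
                for e in self.hyperedges
            ],
        }


@dataclass
class ThresholdNullResult:
    tau_grid: tuple
    real_counts: np.ndarray        # suprathreshold unordered-pair counts per tau
    null_counts: np.ndarray        # n_perm x len(tau_grid)
    fdr: np.ndarray                # mean null / max(real, 1), clipped to [0,1]
    n_permutations: int
    seed: Optional[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tau": self.tau_grid,
                "real_count": self.real_counts,
                "null_mean": self.null_counts.mean(axis=0),
                "null_max": self.null_counts.max(axis=0),
                "fdr": self.fdr,
            }
        )


def pairwise_pearson(m: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between all gene pairs across samples.

    Constant genes get r = 0 against everything (logged) so downstream shapes
    stay stable; the diagonal is forced to 1.
    """
    if m.shape[1] < 3:
        raise ValueError("pairwise correlation requires >= 3 samples")
    x = m.to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.info("pairwise_pearson: %d constant genes set to r=0", int(constant.sum()))
    centred = x - x.mean(axis=1, keepdims=True)
    denom = np.where(constant, 1.0, sd * np.sqrt(m.shape[1]))
    z = centred / denom[:, None]
    r = z @ z.T
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=m.index, columns=m.index)


def build_hypergraph(
    corr: pd.DataFrame,
    tau: float = 0.75,
    weight_mode: str = "seed_anchored",
) -> CoexpressionHypergraph:
    """One ego hyperedge per gene: members {g_j : |r_ij| > tau} plus the seed."""
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0,1)")
    if weight_mode not in ("seed_anchored", "all_pairs"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    genes = list(corr.index)
    a = np.abs(corr.to_numpy(dtype=float))
    np.fill_diagonal(a, 0.0)
    above = a > tau
    edges = []
    for i, seed in enumerate(genes):
        idx = np.flatnonzero(above[i])
        members = frozenset([seed] + [genes[j] for j in idx])
        if weight_mode == "seed_anchored":
            w = float(a[i, idx].sum())
        else:
            rows = np.concatenate(([i], idx))
            sub = a[np.ix_(rows, rows)]
            w = float(np.triu(sub, 1).sum())
        edges.append(Hyperedge(seed=seed, members=members, weight=w))
    return CoexpressionHypergraph(vertices=genes, hyperedges=edges, tau=tau)


def hyperdegree(h: CoexpressionHypergraph) -> pd.Series:
    """deg(g) = sum of weights of hyperedges containing g, descending order."""
    deg = {g: 0.0 for g in h.vertices}
    for e in h.hyperedges:
        for g in e.members:
            deg[g] += e.weight
    s = pd.Series(deg, name="hyperdegree")
    # descending by value, ascending lexicographic within ties
    order = sorted(s.index, key=lambda g: (-s[g], str(g)))
    return s.loc[order]


def top_candidates(ranking: pd.Series, k: int = 300) -> list:
    """First k genes of a hyperdegree ranking (all of them if k exceeds n)."""
    if k > len(ranking):
        logger.info("top_candidates: k=%d > %d genes, returning all", k, len(ranking))
        k = len(ranking)
    return list(ranking.index[:k])


def _suprathreshold_pair_counts(x: np.ndarray, tau_grid: Sequence[float]) -> np.ndarray:
    """Unordered gene-pair counts with |r| above each tau (vectorised)."""
    n = x.shape[1]
    sd = x.std(axis=1)
    keep = sd > 0
    centred = x - x.mean(axis=1, keepdims=True)
    z = np.zeros_like(x)
    z[keep] = centred[keep] / (sd[keep] * np.sqrt(n))[:, None]
    r = z @ z.T
    iu = np.triu_indices(x.shape[0], k=1)
    vals = np.abs(r[iu])
    return np.array([(vals > t).sum() for t in tau_grid], dtype=int)


def permutation_edge_null(
    m: pd.DataFrame,
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
    n_perm: int = 50,
    subsample: int = 1500,
    seed: Optional[int] = None,
) -> ThresholdNullResult:
    """Permutation null for the hyperedge threshold.

    Each permutation shuffles every gene's expression vector independently
    across samples, destroying co-expression while keeping marginals; the
    suprathreshold unordered-pair count is tabulated on the tau grid and the
    empirical FDR at each tau is mean(null count) / max(real count, 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    x = m.to_numpy(dtype=float)
    if subsample and subsample < x.shape[0]:
        rows = rng.choice(x.shape[0], size=subsample, replace=False)
        x = x[rows]
    tau_grid = tuple(float(t) for t in tau_grid)
    real = _suprathreshold_pair_counts(x, tau_grid)
    null = np.empty((n_perm, len(tau_grid)), dtype=int)
    for p in range(n_perm):
        perm = rng.permuted(x, axis=1)
        null[p] = _suprathreshold_pair_counts(perm, tau_grid)
    fdr = np.clip(null.mean(axis=0) / np.maximum(real, 1), 0.0, 1.0)
    return ThresholdNullResult(
        tau_grid=tau_grid, real_counts=real, null_counts=null,
        fdr=fdr, n_permutations=n_perm, seed=seed,
    )
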