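"""Rank-level representational similarity analysis.

Objects are grouped into K ordinal size ranks; a K x K representational
similarity matrix (RSM) is built from the Pearson correlations between
rank-mean response patterns and compared — over its strict upper triangle —
against an *ideal observer* whose similarity decays linearly with rank
distance, ``1 - |i - j| / K``.  A judgment-based RSM built from pairwise
bigger/smaller decisions provides the human-style counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import BinningError, DimensionError, ParameterError, UndefinedStatisticError
from .synthetic import JudgmentMatrix, size_rank_edges


@dataclass
class RankRSM:
    """K x K similarity matrix over size ranks."""

    values: np.ndarray
    n_ranks: int
    kind: str  # response | ideal | judgment

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.n_ranks, self.n_ranks):
            raise DimensionError("values must be n_ranks x n_ranks")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ParameterError("RSM must be symmetric")
        self.values = v

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_ranks, k=1)
        return self.values[iu]

    def to_csv(self, path) -> None:
        labels = [f"rank{r}" for r in range(1, self.n_ranks + 1)]
        pd.DataFrame(self.values, index=labels, columns=labels).to_csv(path)


def assign_size_ranks(sizes_cm, n_ranks: int, min_per_rank: int = 1,
                      size_range: tuple[float, float] | None = None) -> np.ndarray:
    """Assign 1-based size ranks by log-spaced binning.

    Bins are log-spaced over ``size_range`` (default: the observed min/max).
    Raises :class:`BinningError`, naming the first offending rank, when any
    bin holds fewer than ``min_per_rank`` objects.
    """
    sizes = np.asarray(sizes_cm, dtype=float)
    if np.any(sizes <= 0):
        raise ParameterError("sizes must be positive")
    if size_range is None:
        size_range = (float(sizes.min()), float(sizes.max()))
        if size_range[0] == size_range[1]:
            # a single point cannot span n_ranks bins; report the empties
            raise BinningError(
                f"all sizes identical: ranks 2..{n_ranks} would be empty "
                f"({n_ranks - 1} empty ranks)")
    edges = size_rank_edges(size_range, n_ranks)
    ranks = np.digitize(sizes, edges[1:-1], right=False) + 1
    ranks = np.clip(ranks, 1, n_ranks)
    counts = np.bincount(ranks, minlength=n_ranks + 1)[1:]
    bad = np.nonzero(counts < min_per_rank)[0]
    if bad.size:
        raise BinningError(
            f"rank {bad[0] + 1} holds {counts[bad[0]]} objects "
            f"(< min_per_rank={min_per_rank})")
    return ranks


def rank_rsm(responses, ranks) -> RankRSM:
    """RSM of Pearson correlations between rank-mean response patterns."""
    X = np.asarray(getattr(responses, "values", responses), dtype=float)
    ranks = np.asarray(ranks, dtype=int)
    if len(ranks) != X.shape[0]:
        raise DimensionError("ranks not aligned with responses")
    n_ranks = int(ranks.max())
    means = np.empty((n_ranks, X.shape[1]))
    for r in range(1, n_ranks + 1):
        sel = ranks == r
        if not sel.any():
            raise BinningError(f"rank {r} has zero members")
        means[r - 1] = X[sel].mean(axis=0)
    with np.errstate(invalid="ignore"):
        v = np.corrcoef(means)
    if np.any(~np.isfinite(v)):
        raise UndefinedStatisticError("a rank-mean pattern has zero variance")
    np.fill_diagonal(v, 1.0)
    return RankRSM(values=(v + v.T) / 2.0, n_ranks=n_ranks, kind="response")


def ideal_observer_rsm(n_ranks: int) -> RankRSM:
    """Ideal-observer RSM: similarity 1 - |i - j| / K for ranks i, j."""
    if n_ranks < 2:
        raise ParameterError("n_ranks must be >= 2")
    idx = np.arange(1, n_ranks + 1, dtype=float)
    v = 1.0 - np.abs(idx[:, None] - idx[None, :]) / n_ranks
    return RankRSM(values=v, n_ranks=n_ranks, kind="ideal")


def proportional_values(j: JudgmentMatrix) -> np.ndarray:
    """Per-object proportion of pairwise comparisons won (self-term 0,
    denominator n as in the all-pairs design)."""
    return j.indicator.sum(axis=1) / j.n_objects


def judgment_rsm(j: JudgmentMatrix, ranks, denom: float = 8.0) -> RankRSM:
    """Judgment-based RSM: 1 - |Prop_i - Prop_j| / denom over rank-mean
    win proportions.

    The default ``denom=8`` matches the rank-consistency convention; since
    proportions live in [0, 1], entries then sit near 1 — pass
    ``denom="range"`` to rescale by the observed spread of rank proportions.
    """
    ranks = np.asarray(ranks, dtype=int)
    if len(ranks) != j.n_objects:
        raise DimensionError("ranks not aligned with judgment objects")
    prop = proportional_values(j)
    n_ranks = int(ranks.max())
    rank_prop = np.empty(n_ranks)
    for r in range(1, n_ranks + 1):
        sel = ranks == r
        if not sel.any():
            raise BinningError(f"rank {r} has zero members")
        rank_prop[r - 1] = prop[sel].mean()
    if denom == "range":
        spread = rank_prop.max() - rank_prop.min()
        if spread == 0:
            raise UndefinedStatisticError("rank proportions are constant")
        denom = spread
    v = 1.0 - np.abs(rank_prop[:, None] - rank_prop[None, :]) / float(denom)
    return RankRSM(values=v, n_ranks=n_ranks, kind="judgment")


def rsm_correspondence(a: RankRSM, b: RankRSM) -> float:
    """Pearson correlation between the strict upper triangles of two RSMs.

    The diagonal is excluded because response-RSM diagonals are identically 1.
    """
    if a.n_ranks != b.n_ranks:
        raise DimensionError("RSMs have different numbers of ranks")
    ua, ub = a.upper_triangle(), b.upper_triangle()
    if np.ptp(ua) == 0 or np.ptp(ub) == 0:
        raise UndefinedStatisticError("constant upper triangle: correlation undefined")
    return float(np.corrcoef(ua, ub)[0, 1])
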