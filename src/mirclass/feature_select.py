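"""Correlation-based feature-subset selection (CFS) with best-first search.

A candidate subset S of k features is scored by the merit

    Merit(S) = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)

where r̄_cf is the mean feature–class correlation and r̄_ff the mean pairwise
feature–feature correlation within S, both measured by symmetric uncertainty

    SU(X, Y) = 2·(H(X) + H(Y) − H(X, Y)) / (H(X) + H(Y)),

the normalized mutual information (0 when both marginal entropies vanish).
High merit rewards subsets whose members predict the class individually but
are mutually non-redundant.  Numeric columns are discretized by
equal-frequency binning before entropies are taken.  The search is greedy
best-first forward selection, stopping after a fixed number of consecutive
non-improving expansions; no hard cap on subset size is imposed.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np

from .core import FeatureTable

logger = logging.getLogger(__name__)

N_BINS_DEFAULT = 10
STALE_LIMIT_DEFAULT = 5


def discretize(column: np.ndarray, n_bins: int = N_BINS_DEFAULT) -> np.ndarray:
    """Equal-frequency binning of a numeric column into integer codes.

    Columns whose values are already a small integer set (e.g. one-hot 0/1)
    are returned as codes unchanged; constant columns map to a single code.
    """
    column = np.asarray(column, dtype=float)
    uniq = np.unique(column)
    if len(uniq) <= n_bins:
        return np.searchsorted(uniq, column)
    qs = np.quantile(column, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, column, side="left")


def _entropy(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _joint_entropy(x: np.ndarray, y: np.ndarray) -> float:
    # pair codes via a collision-free linear combination
    joint = x.astype(np.int64) * (int(y.max()) + 1) + y.astype(np.int64)
    return _entropy(joint)


def symmetric_uncertainty(x: np.ndarray, y: np.ndarray) -> float:
    """SU between two discrete columns, in [0, 1].

    Inputs are integer code vectors of equal length; 0 when both columns are
    constant (both entropies zero).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    hx, hy = _entropy(x), _entropy(y)
    denom = hx + hy
    if denom == 0.0:
        return 0.0
    mi = hx + hy - _joint_entropy(x, y)
    su = 2.0 * mi / denom
    # clamp tiny negative drift from floating-point entropy sums
    return float(min(1.0, max(0.0, su)))


class _SUCache:
    """Discretized columns plus lazily computed SU values for one table."""

    def __init__(self, table: FeatureTable, n_bins: int = N_BINS_DEFAULT):
        self.codes = [
            discretize(table.matrix[:, j], n_bins) for j in range(table.n_features)
        ]
        self.y = table.y()
        self.su_cf = np.array(
            [symmetric_uncertainty(c, self.y) for c in self.codes]
        )
        self._ff: dict[tuple[int, int], float] = {}

    def su_ff(self, i: int, j: int) -> float:
        key = (i, j) if i < j else (j, i)
        if key not in self._ff:
            self._ff[key] = symmetric_uncertainty(self.codes[key[0]], self.codes[key[1]])
        return self._ff[key]


def _merit_from_sums(k: int, sum_cf: float, sum_ff: float) -> float:
    if k == 0:
        raise ValueError("empty subset has no merit")
    denom = np.sqrt(k + 2.0 * sum_ff)
    if denom == 0.0:
        return 0.0
    return float(sum_cf / denom)


def merit_of(subset: list[int], table: FeatureTable, _cache: _SUCache | None = None) -> float:
    """CFS merit of a feature subset.

    For k = 1 this reduces to SU(feature, class); the pairwise term is
    vacuous.  Raises on an empty subset.
    """
    if len(subset) == 0:
        raise ValueError("empty subset has no merit")
    cache = _cache if _cache is not None else _SUCache(table)
    sum_cf = float(cache.su_cf[list(subset)].sum())
    sum_ff = 0.0
    for a in range(len(subset)):
        for b in range(a + 1, len(subset)):
            sum_ff += cache.su_ff(subset[a], subset[b])
    return _merit_from_sums(len(subset), sum_cf, sum_ff)


@dataclass
class SelectedSubset:
    """Result of subset selection: surviving indices and the search trace."""

    feature_indices: list[int]
    merit: float
    search_trace: list[tuple[tuple[int, ...], float]] = field(default_factory=list)

    def feature_names(self, table: FeatureTable) -> list[str]:
        return [table.feature_names[j] for j in self.feature_indices]


def best_first_select(
    table: FeatureTable,
    stale_limit: int = STALE_LIMIT_DEFAULT,
    max_features: int | None = None,
) -> SelectedSubset:
    """Greedy best-first forward search maximizing CFS merit.

    Starts from singletons, repeatedly expands the best unexpanded subset by
    one feature, and stops after ``stale_limit`` consecutive expansions that
    fail to improve the global best.  Deterministic: ties are broken toward
    the lower feature index.  If no feature has positive merit (e.g. all
    columns constant), the selection is empty with merit 0.
    ``max_features`` optionally caps subset size.
    """
    if table.n_features < 1:
        raise ValueError("table has no features")
    cache = _SUCache(table)
    trace: list[tuple[tuple[int, ...], float]] = []

    # seed: best singleton
    best_j = int(np.lexsort((np.arange(table.n_features), -cache.su_cf))[0])
    best_merit = float(cache.su_cf[best_j])
    if best_merit <= 0.0:
        logger.warning("no feature carries class information; empty selection")
        return SelectedSubset(feature_indices=[], merit=0.0, search_trace=trace)
    best_subset = (best_j,)
    trace.append((best_subset, best_merit))

    # priority queue of (−merit, subset, sum_cf, sum_ff); lexicographic subset
    # order makes tie-breaks deterministic
    frontier: list[tuple[float, tuple[int, ...], float, float]] = []
    heapq.heappush(frontier, (-best_merit, best_subset, best_merit, 0.0))
    expanded: set[tuple[int, ...]] = set()
    stale = 0

    while frontier and stale < stale_limit:
        neg_m, subset, sum_cf, sum_ff = heapq.heappop(frontier)
        if subset in expanded:
            continue
        expanded.add(subset)
        if max_features is not None and len(subset) >= max_features:
            continue
        improved = False
        in_subset = set(subset)
        for j in range(table.n_features):
            if j in in_subset or cache.su_cf[j] <= 0.0:
                continue
            new_cf = sum_cf + float(cache.su_cf[j])
            new_ff = sum_ff + sum(cache.su_ff(i, j) for i in subset)
            child = tuple(sorted(in_subset | {j}))
            m = _merit_from_sums(len(child), new_cf, new_ff)
            trace.append((child, m))
            if m > best_merit + 1e-12:
                best_merit, best_subset = m, child
                improved = True
            heapq.heappush(frontier, (-m, child, new_cf, new_ff))
        stale = 0 if improved else stale + 1

    return SelectedSubset(
        feature_indices=list(best_subset),
        merit=best_merit,
        search_trace=trace,
    )


def selection_report(subset: SelectedSubset, table: FeatureTable) -> dict:
    """JSON-ready summary: selected features with kinds and the merit trace."""
    return {
        "n_selected": len(subset.feature_indices),
        "merit": subset.merit,
        "features": [
            {
                "index": j,
                "name": table.feature_names[j],
                "kind": table.column_kinds[j],
            }
            for j in subset.feature_indices
        ],
        "trace_tail": [
            {"subset": list(s), "merit": m} for s, m in subset.search_trace[-20:]
        ],
    }
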