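"""Conversion orders from natural-breaks classification of capabilities.

The conversion order L[j,d] is the ordinal priority of land system j for
filling the demand-supply gap of service d (-1 = of no use).  Instead of
hand-tuning these integers, they are derived automatically: the capability
column {S[j,d]}_j is classified by Jenks natural breaks, with the number of
classes K chosen adaptively — K grows from 2 until the best classification's
goodness of variance fit (GVF = 1 - SDCM/SDAM) exceeds a threshold (default
0.8) — and a value in the κ-th class (classes ordered by mean) receives
order κ-1.  A rank-based benchmark (competition ranking of the nonzero
capabilities, zeros mapped to -1) is provided for comparison.

Classification conventions: classes are contiguous runs of the sorted
multiset; breaks are never placed between equal values, so tied capabilities
always share an order; among GVF-maximising schemes the one with the fewest
values in the top class wins, then the lexicographically smallest break
vector.  Near-equal GVFs (within 1e-9 relative to SDAM) count as ties.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "ClassScheme",
    "gvf",
    "best_partition",
    "adaptive_classify",
    "orders_from_classes",
    "derive_orders",
    "benchmark_orders",
]

_TIE_TOL = 1e-9
# above this many break combinations, enumeration hands over to dynamic
# programming (same optimum and tie rules, reconstructed greedily)
_ENUM_LIMIT = 500_000


@dataclass(frozen=True)
class ClassScheme:
    """A contiguous K-class partition of a univariate multiset.

    ``breaks`` are indices into the sorted values: class x spans
    ``sorted_values[breaks[x-1]:breaks[x]]`` with implicit ends 0 and n.
    Class means are strictly increasing because the data are sorted and no
    break separates equal values.
    """

    original: np.ndarray
    sorted_values: np.ndarray
    breaks: tuple[int, ...]
    gvf: float

    @property
    def K(self) -> int:
        return len(self.breaks) + 1

    @property
    def classes(self) -> list[np.ndarray]:
        edges = (0, *self.breaks, len(self.sorted_values))
        return [self.sorted_values[a:b] for a, b in zip(edges[:-1], edges[1:])]

    @property
    def class_means(self) -> np.ndarray:
        return np.array([c.mean() for c in self.classes])

    def assign(self, values: np.ndarray | None = None) -> np.ndarray:
        """0-based class index of each value (defaults to the original input)."""
        v = self.original if values is None else np.asarray(values, dtype=float)
        uppers = np.array([c[-1] for c in self.classes[:-1]])
        return np.searchsorted(uppers, v, side="left").astype(np.int64)


def _prefix_sums(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return np.concatenate([[0.0], np.cumsum(v)]), np.concatenate([[0.0], np.cumsum(v * v)])


def _sse(s1: np.ndarray, s2: np.ndarray, a: int, b: int) -> float:
    n = b - a
    t = s1[b] - s1[a]
    return (s2[b] - s2[a]) - t * t / n


def _sdam(v: np.ndarray) -> float:
    return float(((v - v.mean()) ** 2).sum())


def gvf(values, scheme: "ClassScheme | list[np.ndarray]") -> float:
    """Goodness of variance fit, 1 - SDCM/SDAM; 1 when all values are equal."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty input")
    classes = scheme.classes if isinstance(scheme, ClassScheme) else scheme
    sdam = _sdam(v)
    if sdam == 0:
        return 1.0
    sdcm = sum(float(((c - c.mean()) ** 2).sum()) for c in classes)
    return 1.0 - sdcm / sdam


def _allowed_breaks(v: np.ndarray) -> np.ndarray:
    """Indices i where a break before sorted position i is allowed (v[i-1] != v[i])."""
    return np.nonzero(np.diff(v) != 0)[0] + 1


def best_partition(values, K: int) -> ClassScheme:
    """GVF-maximising contiguous partition of ``values`` into K classes.

    Enumerates every placement of K-1 breaks between unequal neighbours of
    the sorted multiset (the general natural-breaks algorithm); very large
    enumerations are solved by an equivalent dynamic program.
    """
    orig = np.asarray(values, dtype=float).ravel()
    if orig.size == 0:
        raise ValueError("empty input")
    v = np.sort(orig)
    allowed = _allowed_breaks(v)
    n_distinct = len(allowed) + 1
    if not 1 <= K <= n_distinct:
        raise ValueError(f"K={K} outside 1..{n_distinct} (distinct values)")
    sdam = _sdam(v)
    if K == 1 or sdam == 0:
        return ClassScheme(orig, v, (), 1.0 if sdam == 0 else 0.0)
    if K == n_distinct:
        breaks = tuple(int(b) for b in allowed)
        return ClassScheme(orig, v, breaks, 1.0)
    s1, s2 = _prefix_sums(v)
    tol = _TIE_TOL * max(1.0, sdam)
    if math.comb(len(allowed), K - 1) <= _ENUM_LIMIT:
        breaks = _enumerate_best(v, s1, s2, allowed, K, tol)
    else:
        breaks = _dp_best(v, s1, s2, allowed, K, tol)
    sdcm = 0.0
    edges = (0, *breaks, len(v))
    for a, b in zip(edges[:-1], edges[1:]):
        sdcm += _sse(s1, s2, a, b)
    return ClassScheme(orig, v, tuple(int(b) for b in breaks), 1.0 - sdcm / sdam)


def _enumerate_best(v, s1, s2, allowed, K, tol) -> tuple[int, ...]:
    n = len(v)
    best_sdcm = math.inf
    best: tuple[int, ...] | None = None
    for combo in combinations(allowed.tolist(), K - 1):
        edges = (0, *combo, n)
        sdcm = 0.0
        for a, b in zip(edges[:-1], edges[1:]):
            sdcm += _sse(s1, s2, a, b)
            if sdcm > best_sdcm + tol:
                break
        if sdcm < best_sdcm - tol:
            best_sdcm, best = sdcm, combo
        elif sdcm <= best_sdcm + tol and best is not None:
            best_sdcm = min(best_sdcm, sdcm)
            # tie: fewest values in the top class, then lexicographically
            # smallest break vector (combinations are generated in lexical
            # order, so only a strictly later last break wins)
            if combo[-1] > best[-1]:
                best = combo
    assert best is not None
    return best


def _dp_best(v, s1, s2, allowed, K, tol) -> tuple[int, ...]:
    """Min-SDCM dynamic program with the same tie rules as enumeration."""
    n = len(v)
    pos = [0, *allowed.tolist(), n]
    m = len(pos)
    INF = math.inf
    # fwd[k][i]: min SDCM of v[0:pos[i]] in k classes
    fwd = np.full((K, m), INF)
    for i in range(1, m):
        fwd[0][i] = _sse(s1, s2, 0, pos[i])
    for k in range(1, K):
        for i in range(k + 1, m):
            best = INF
            for j in range(k, i):
                cand = fwd[k - 1][j] + _sse(s1, s2, pos[j], pos[i])
                if cand < best:
                    best = cand
            fwd[k][i] = best
    opt = fwd[K - 1][m - 1]
    # last break as late as possible (fewest values in the top class)
    bl = max(
        i
        for i in range(K - 1, m - 1)
        if fwd[K - 2][i] + _sse(s1, s2, pos[i], n) <= opt + tol
    )
    if K == 2:
        return (pos[bl],)
    # backward table g[k][i]: min SDCM of v[pos[i]:pos[bl]] in k+1 classes
    g = np.full((K - 1, m), INF)
    for i in range(bl):
        g[0][i] = _sse(s1, s2, pos[i], pos[bl])
    for k in range(1, K - 1):
        for i in range(bl):
            best = INF
            for j in range(i + 1, bl):
                cand = _sse(s1, s2, pos[i], pos[j]) + g[k - 1][j]
                if cand < best:
                    best = cand
            g[k][i] = best
    target = fwd[K - 2][bl]
    breaks: list[int] = []
    acc, cur = 0.0, 0
    for x in range(K - 2):
        for j in range(cur + 1, bl):
            cand = acc + _sse(s1, s2, pos[cur], pos[j]) + g[K - 3 - x][j]
            if cand <= target + tol:
                breaks.append(pos[j])
                acc += _sse(s1, s2, pos[cur], pos[j])
                cur = j
                break
    breaks.append(pos[bl])
    return tuple(breaks)


def adaptive_classify(values, gvf_threshold: float = 0.8) -> ClassScheme:
    """Natural breaks with the number of classes chosen adaptively.

    K runs from 2 upward; the first K whose best partition has
    GVF strictly greater than ``gvf_threshold`` is returned.  If no K
    qualifies (possible only when the threshold is 1), the all-singleton
    scheme is returned with a warning.  Inputs with at most one distinct
    value yield a single class with GVF 1.
    """
    if not 0 < gvf_threshold <= 1:
        raise ValueError("gvf_threshold must be in (0, 1]")
    orig = np.asarray(values, dtype=float).ravel()
    if orig.size == 0:
        raise ValueError("empty input")
    n_distinct = len(np.unique(orig))
    if n_distinct <= 1:
        return best_partition(orig, 1)
    for K in range(2, n_distinct + 1):
        scheme = best_partition(orig, K)
        # strictly greater; the guard keeps a GVF that is exactly the
        # threshold up to round-off from passing on summation-order noise
        if scheme.gvf > gvf_threshold + 1e-12:
            return scheme
    warnings.warn(
        "no classification exceeded the GVF threshold; returning singleton classes",
        stacklevel=2,
    )
    return best_partition(orig, n_distinct)


def orders_from_classes(scheme: ClassScheme, zero_as_minus_one: bool = False) -> np.ndarray:
    """Translate a class scheme into conversion orders: class κ -> order κ-1.

    With ``zero_as_minus_one``, values exactly 0 (systems that cannot supply
    the service at all) get order -1 instead.
    """
    out = scheme.assign()
    if zero_as_minus_one:
        out = np.where(scheme.original == 0, -1, out)
    return out.astype(np.int64)


def derive_orders(
    capabilities: pd.DataFrame,
    gvf_threshold: float = 0.8,
    zero_as_minus_one: bool = False,
) -> pd.DataFrame:
    """Conversion-order matrix via adaptive natural breaks, per service column."""
    cols = {}
    for svc in capabilities.columns:
        col = capabilities[svc].to_numpy(dtype=float)
        if (col == 0).all():
            warnings.warn(f"all-zero capability column {svc!r}", stacklevel=2)
        scheme = adaptive_classify(col, gvf_threshold)
        cols[svc] = orders_from_classes(scheme, zero_as_minus_one)
    return pd.DataFrame(cols, index=capabilities.index)


def benchmark_orders(capabilities: pd.DataFrame) -> pd.DataFrame:
    """Rank-based benchmark orders.

    Per service: zero capability -> -1; otherwise the ascending competition
    rank (starting at 1) among the nonzero capabilities of that service —
    ties share the lower rank and the next rank is skipped.
    """
    cols = {}
    for svc in capabilities.columns:
        col = capabilities[svc].to_numpy(dtype=float)
        out = np.full(col.shape, -1, dtype=np.int64)
        nz = col != 0
        nzvals = col[nz]
        # competition rank = 1 + number of strictly smaller nonzero values
        out[nz] = 1 + (nzvals[:, None] > nzvals[None, :]).sum(axis=1)
        cols[svc] = out
    return pd.DataFrame(cols, index=capabilities.index)
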