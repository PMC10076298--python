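"""Conversion resistance and the conversion-allowance matrix from history.

Resistance P_res[j] is the historically observed persistence of type j
between two dates: the fraction of j-cells at h1 that are still j at h2.
The allowance matrix Con[a,b] permits a conversion a->b only when it was
observed on more than a threshold share (default 1%) of the study area
between the two dates; the diagonal is always allowed.
"""

from __future__ import annotations

import warnings

import numpy as np

from .grids import LandSystemMap, require_aligned

__all__ = ["estimate_resistance", "build_conversion_matrix"]


def _check_pair(map_h1: LandSystemMap, map_h2: LandSystemMap) -> None:
    require_aligned(map_h1.grid, map_h2.grid)
    if map_h1.legend != map_h2.legend:
        raise ValueError("historical maps must share the same legend")


def estimate_resistance(map_h1: LandSystemMap, map_h2: LandSystemMap) -> np.ndarray:
    """P_res[j] = persisted j-cells / j-cells at h1, in [0,1].

    Types absent at h1 get resistance 0 with a warning.
    """
    _check_pair(map_h1, map_h2)
    n = map_h1.n
    valid = (~map_h1.grid.mask) & (~map_h2.grid.mask)
    a = map_h1.grid.values[valid]
    b = map_h2.grid.values[valid]
    at_h1 = np.bincount(a, minlength=n).astype(float)
    persisted = np.bincount(a[a == b], minlength=n).astype(float)
    absent = np.flatnonzero(at_h1 == 0)
    if absent.size:
        warnings.warn(
            f"types absent at h1 get resistance 0: {[map_h1.legend[int(j)] for j in absent]}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        res = np.where(at_h1 > 0, persisted / np.maximum(at_h1, 1), 0.0)
    return res


def build_conversion_matrix(
    map_h1: LandSystemMap, map_h2: LandSystemMap, threshold_pct: float = 1.0
) -> np.ndarray:
    """0/1 allowance matrix from observed conversions.

    Con[a,b] = 1 iff the a->b conversion covered more than ``threshold_pct``
    percent of the non-nodata study area; Con[j,j] = 1 always.
    """
    _check_pair(map_h1, map_h2)
    n = map_h1.n
    valid = (~map_h1.grid.mask) & (~map_h2.grid.mask)
    a = map_h1.grid.values[valid]
    b = map_h2.grid.values[valid]
    total = valid.sum()
    counts = np.bincount(a * n + b, minlength=n * n).reshape(n, n)
    con = (counts / total * 100.0 > threshold_pct).astype(np.int64)
    np.fill_diagonal(con, 1)
    return con
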