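"""Categorical map agreement: Kappa and total (quantity + allocation) disagreement."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .grids import LandSystemMap, require_aligned

__all__ = ["crosstab", "kappa", "total_disagreement", "class_sweep"]


def crosstab(sim: LandSystemMap, ref: LandSystemMap) -> np.ndarray:
    """Confusion matrix of area proportions, p[i,j] = share simulated i / reference j.

    Computed over cells valid in both maps; sums to 1.
    """
    require_aligned(sim.grid, ref.grid)
    if sim.legend != ref.legend:
        raise ValueError("maps must share the same legend")
    n = sim.n
    valid = (~sim.grid.mask) & (~ref.grid.mask)
    if not valid.any():
        raise ValueError("no jointly valid cells")
    a = sim.grid.values[valid]
    b = ref.grid.values[valid]
    counts = np.bincount(a * n + b, minlength=n * n).reshape(n, n)
    return counts / counts.sum()


def kappa(cm: np.ndarray) -> float | None:
    """Chance-corrected agreement (P0 - Pe)/(1 - Pe); None when Pe = 1."""
    p0 = np.trace(cm)
    pe = float(cm.sum(axis=1) @ cm.sum(axis=0))
    if pe == 1.0:
        return None
    return float((p0 - pe) / (1.0 - pe))


def total_disagreement(cm: np.ndarray) -> float:
    """D = 0.5 (Σ_g q_g + Σ_g a_g): quantity plus allocation disagreement.

    q_g = |colsum_g - rowsum_g|; a_g = 2 min(colsum_g - p_gg, rowsum_g - p_gg).
    Smaller is better; 0 only at perfect agreement.
    """
    rows = cm.sum(axis=1)
    cols = cm.sum(axis=0)
    diag = np.diag(cm)
    q = np.abs(cols - rows)
    a = 2.0 * np.minimum(cols - diag, rows - diag)
    return float(0.5 * (q.sum() + a.sum()))


def class_sweep(study, K_range, seed: int = 0) -> pd.DataFrame:
    """Re-run the simulation across fixed class numbers K for the order derivation.

    For each K, conversion orders come from the general natural-breaks
    partition with exactly K classes per service column, one simulation is
    run, and both agreement metrics against the reference map are recorded.
    K values the classification cannot produce, or where the engine
    stagnates (notably K = 1, where all orders are equal and competition is
    inert), are recorded as missing with a reason.
    """
    from .orders import best_partition, orders_from_classes
    from .pipeline import simulate_study

    rows = []
    cap = study.capability
    for K in K_range:
        reason = None
        orders = np.zeros(cap.shape, dtype=np.int64)
        for di, svc in enumerate(cap.columns):
            col = cap[svc].to_numpy(dtype=float)
            n_distinct = len(np.unique(col))
            kk = min(K, n_distinct)
            orders[:, di] = orders_from_classes(best_partition(col, kk))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = simulate_study(study, orders, seed=seed)
        if res.stagnated:
            reason = "stagnated: all conversion orders equal, no usable simulation"
            rows.append({"K": K, "kappa": np.nan, "disagreement": np.nan, "reason": reason})
            continue
        cm = crosstab(res.map, study.reference_map)
        rows.append(
            {
                "K": K,
                "kappa": kappa(cm),
                "disagreement": total_disagreement(cm),
                "reason": "" if res.converged else "iteration cap reached",
            }
        )
    return pd.DataFrame(rows)
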