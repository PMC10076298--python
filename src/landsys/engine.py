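"""Iterative demand-supply allocation.

Each simulated time step runs many iterations.  In iteration i every cell
is (synchronously) re-decided: its transition potential toward type j is
P_loc[c,j] (logistic suitability) + P_cmp[T0(c),j] (competitive advantage)
plus the conversion resistance P_res[T0(c)] when j is the cell's
start-of-step type T0(c).  The competitive advantage steers cells toward
types whose conversion orders are higher for currently under-supplied
services:

    P_cmp[j0,j] = sum_d sign(L[j,d] - L[j0,d]) * ω_d * diff_d

where diff accumulates the speed-damped relative demand-supply gap

    diff_d <- diff_d - ((Supply_d - Demand_d)/Demand_d) / (Speed_i * R_i),

Speed grows linearly from 0.05 by 0.0002 per iteration and R_i is a fresh
uniform integer in [322, 365] each iteration.  The step converges when the
mean absolute relative gap is below 0.5% and every service's gap is below
1%; the iteration cap defaults to 20,000.

Cell updates are synchronous from the frozen previous-iteration state, so
visiting order is irrelevant; argmax ties break to the lowest type id.
Restricted cells and cells under the minimum dwell time τ never change.
A candidate forbidden by the conversion-allowance matrix leaves the cell at
its previous-iteration type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import Grid, LandSystemMap, RegionMask

__all__ = [
    "SimulationConfig",
    "TimeStepResult",
    "SimulationResult",
    "compute_supply",
    "competitive_advantage",
    "transition_potential",
    "select_type",
    "update_diff",
    "advance_speed",
    "draw_R",
    "check_convergence",
    "run_time_step",
    "run_simulation",
]


@dataclass
class SimulationConfig:
    max_iterations: int = 20_000
    mean_tolerance: float = 0.005  # mean |relative gap| over services
    per_service_tolerance: float = 0.01  # every service's |relative gap|
    speed_init: float = 0.05
    speed_increment: float = 0.0002
    R_low: int = 322
    R_high: int = 365
    rng_seed: int = 0
    dwell_min: np.ndarray | None = None  # τ[j], minimum dwell time steps
    weights: np.ndarray | None = None  # ω_d, default 1

    def __post_init__(self) -> None:
        if self.mean_tolerance <= 0 or self.per_service_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if self.R_low > self.R_high:
            raise ValueError("R_low must be <= R_high")
        if self.dwell_min is not None:
            self.dwell_min = np.asarray(self.dwell_min)
            if (self.dwell_min < 0).any():
                raise ValueError("dwell minimums must be >= 0")


@dataclass
class TimeStepResult:
    """Outcome of one simulated time step."""

    map: LandSystemMap
    converged: bool
    stagnated: bool
    iterations: int
    supply: np.ndarray
    trace: pd.DataFrame  # per-iteration Supply_d and diff_d
    age: np.ndarray

    def summary(self) -> str:
        status = "converged" if self.converged else ("stagnated" if self.stagnated else "hit cap")
        return (
            f"time step {status} after {self.iterations} iteration(s); "
            f"final supply: {np.array2string(self.supply, precision=4)}"
        )


@dataclass
class SimulationResult:
    maps: list[LandSystemMap]
    steps: list[TimeStepResult]
    provenance: dict


def compute_supply(ls_map: LandSystemMap, cap: np.ndarray, cell_area: float) -> np.ndarray:
    """Supply_d = Σ_cells S[T(c), d] × cell_area over non-nodata cells."""
    if cap.shape[0] != ls_map.n:
        raise ValueError("capability rows do not match the legend")
    counts = ls_map.counts().astype(float)
    return (counts * cell_area) @ cap


def _pcmp_matrix(orders: np.ndarray, weights: np.ndarray, diff: np.ndarray) -> np.ndarray:
    """P_cmp[j0, j] for every (start type, candidate type) pair."""
    sign = np.sign(orders[None, :, :] - orders[:, None, :]).astype(float)
    return sign @ (weights * diff)


def competitive_advantage(
    j: int, j0: int, orders: np.ndarray, weights: np.ndarray, diff: np.ndarray
) -> float:
    """Σ_d sign(L[j,d] - L[j0,d]) ω_d diff_d."""
    return float(np.sign(orders[j] - orders[j0]).astype(float) @ (weights * diff))


def transition_potential(p_loc: float, p_res: float, p_cmp: float, same_type: bool) -> float:
    """Linear combination of suitability, resistance (incumbent only) and competition."""
    return p_loc + p_cmp + (p_res if same_type else 0.0)


def select_type(
    potentials: np.ndarray,
    start_type: int,
    prev_type: int,
    restricted: bool,
    con: np.ndarray,
    age: int = 0,
    dwell_min: int = 0,
) -> int:
    """Single-cell update rule with the three restrictions.

    Restricted cells and cells that have not dwelt τ steps keep their
    start-of-step type; otherwise the potential argmax (ties -> lowest id)
    is adopted if the conversion from the previous-iteration type is
    allowed, else the previous-iteration type is kept.
    """
    if restricted or age < dwell_min:
        return start_type
    k = int(np.argmax(potentials))
    return k if con[prev_type, k] == 1 else prev_type


def update_diff(
    diff_prev: np.ndarray,
    supply: np.ndarray,
    demand: np.ndarray,
    speed: float,
    R: float,
) -> np.ndarray:
    """Speed-damped accumulation of the relative demand-supply gap.

    Services with zero demand keep diff = 0 (and are excluded from
    convergence checks by the caller).
    """
    if not (np.isfinite(supply).all() and np.isfinite(diff_prev).all()):
        raise FloatingPointError("non-finite supply or diff")
    out = np.array(diff_prev, dtype=float)
    active = demand > 0
    gap = (supply[active] - demand[active]) / demand[active]
    out[active] = diff_prev[active] - gap / (speed * R)
    out[~active] = 0.0
    return out


def advance_speed(speed_prev: float, increment: float = 0.0002) -> float:
    return speed_prev + increment


def draw_R(rng: np.random.Generator, low: int = 322, high: int = 365) -> int:
    """One uniform integer draw per iteration, shared by all services."""
    if low > high:
        raise ValueError("low must be <= high")
    return int(rng.integers(low, high + 1))


def check_convergence(
    supply: np.ndarray, demand: np.ndarray, config: SimulationConfig
) -> bool:
    """Mean |relative gap| < mean_tolerance and every gap < per_service_tolerance.

    Absolute deviations are used on both conditions so oversupply cannot
    fake convergence.  Zero-demand services are excluded.
    """
    active = demand > 0
    if not active.any():
        return True
    rel = np.abs(supply[active] - demand[active]) / demand[active]
    return bool(rel.mean() < config.mean_tolerance and (rel < config.per_service_tolerance).all())


def run_time_step(
    start_map: LandSystemMap,
    p_loc: np.ndarray,
    p_res: np.ndarray,
    orders: np.ndarray,
    con: np.ndarray,
    demand: np.ndarray,
    cap: np.ndarray,
    config: SimulationConfig,
    mask: RegionMask | None = None,
    age: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> TimeStepResult:
    """Run the allocation iterations of a single time step.

    ``p_loc`` is an (n_types, nrows, ncols) suitability array, ``p_res`` the
    per-type resistance vector, ``orders`` the (n_types, n_services) integer
    conversion-order matrix, ``con`` the 0/1 allowance matrix and ``cap``
    the (n_types, n_services) capability matrix.  Returns the end-of-step
    map plus convergence diagnostics and the per-iteration trace.
    """
    n = start_map.n
    grid = start_map.grid
    if p_loc.shape != (n, grid.nrows, grid.ncols):
        raise ValueError("suitability array shape mismatch")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    weights = (
        np.ones(len(demand)) if config.weights is None else np.asarray(config.weights, float)
    )
    dwell = (
        np.zeros(n, dtype=int) if config.dwell_min is None else np.asarray(config.dwell_min, int)
    )
    if age is None:
        age = np.zeros(grid.values.shape, dtype=np.int64)

    valid = ~grid.mask
    cells = np.flatnonzero(valid.ravel())
    T0 = grid.values.ravel()[cells]
    ploc_cells = p_loc.reshape(n, -1)[:, cells]  # (n, ncells)
    restricted = (
        mask.restricted.ravel()[cells] if mask is not None else np.zeros(len(cells), bool)
    )
    locked = restricted | (age.ravel()[cells] < dwell[T0])
    incumbent_bonus = np.zeros_like(ploc_cells)
    incumbent_bonus[T0, np.arange(len(cells))] = p_res[T0]
    base = ploc_cells + incumbent_bonus
    cell_area = grid.cell_area_km2

    # all orders equal within every service => P_cmp is identically zero and
    # the competition can never move the map: stagnation unless already there
    competitive = bool((orders.max(axis=0) != orders.min(axis=0)).any())

    diff = np.zeros(len(demand))
    speed = config.speed_init
    T_prev = T0.copy()
    trace_rows = []
    converged = False
    stagnated = False
    i = 0
    while True:
        i += 1
        pcmp = _pcmp_matrix(orders, weights, diff)  # (j0, j)
        potentials = base + pcmp[T0].T
        k = np.argmax(potentials, axis=0)  # first occurrence = lowest id
        allowed = con[T_prev, k] == 1
        T_new = np.where(allowed, k, T_prev)
        T_new[locked] = T0[locked]
        counts = np.bincount(T_new, minlength=n).astype(float)
        supply = (counts * cell_area) @ cap
        trace_rows.append((i, *supply, *diff))
        if check_convergence(supply, demand, config):
            converged = True
            T_prev = T_new
            break
        if not competitive:
            stagnated = True
            warnings.warn(
                "all conversion orders are equal: competition cannot adjust supply "
                "(stagnation)",
                stacklevel=2,
            )
            T_prev = T_new
            break
        if i >= config.max_iterations:
            warnings.warn(
                f"no convergence within {config.max_iterations} iterations", stacklevel=2
            )
            T_prev = T_new
            break
        R = draw_R(rng, config.R_low, config.R_high)
        diff = update_diff(diff, supply, demand, speed, R)
        speed = advance_speed(speed, config.speed_increment)
        T_prev = T_new

    end_vals = np.array(grid.values)
    end_vals.ravel()[cells] = T_prev
    end_map = LandSystemMap(grid.like(end_vals), dict(start_map.legend))
    new_age = np.where(end_vals == grid.values, age + 1, 0)
    new_age[grid.mask] = 0
    services = [f"s{d}" for d in range(len(demand))]
    trace = pd.DataFrame(
        trace_rows,
        columns=["iteration"] + [f"supply_{s}" for s in services] + [f"diff_{s}" for s in services],
    )
    return TimeStepResult(end_map, converged, stagnated, i, supply, trace, new_age)


def run_simulation(
    initial_map: LandSystemMap,
    demand_table: pd.DataFrame,
    p_loc: np.ndarray,
    p_res: np.ndarray,
    orders: np.ndarray,
    con: np.ndarray,
    cap: np.ndarray,
    config: SimulationConfig,
    mask: RegionMask | None = None,
) -> SimulationResult:
    """Chain time steps over the demand series (one row per step)."""
    rng = np.random.default_rng(config.rng_seed)
    maps = [initial_map]
    steps: list[TimeStepResult] = []
    age = np.zeros(initial_map.grid.values.shape, dtype=np.int64)
    for step in demand_table.index:
        demand = demand_table.loc[step].to_numpy(dtype=float)
        res = run_time_step(
            maps[-1], p_loc, p_res, orders, con, demand, cap, config, mask, age, rng
        )
        age = res.age
        maps.append(res.map)
        steps.append(res)
    provenance = {
        "rng_seed": config.rng_seed,
        "max_iterations": config.max_iterations,
        "steps": [
            {"step": int(s), "converged": r.converged, "iterations": r.iterations}
            for s, r in zip(demand_table.index, steps)
        ],
    }
    return SimulationResult(maps, steps, provenance)
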