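"""End-to-end orchestration: taxonomy -> suitability -> dynamics -> orders ->
allocation -> evaluation, for synthetic or file-based study areas."""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import SimulationConfig, TimeStepResult, run_time_step
from .evaluate import crosstab, kappa, total_disagreement
from .grids import (
    AlignmentError,
    FactorStack,
    Grid,
    LandSystemMap,
    read_ascii_grid,
    read_table,
    require_aligned,
    write_ascii_grid,
)
from .landsystems import (
    aggregate_blocks,
    apply_taxonomy,
    capability_matrix,
    demand_from_map,
    derive_taxonomy,
)
from .orders import benchmark_orders, derive_orders
from .resistance import build_conversion_matrix, estimate_resistance
from .suitability import SuitabilityModel, fit_suitability, predict_suitability
from .synth import FixtureSpec, make_factor_stack, make_history_pair

__all__ = ["Study", "make_study", "simulate_study", "validate_config", "run_pipeline"]


@dataclass
class Study:
    """Everything one simulated time step needs, plus the reference map."""

    initial_map: LandSystemMap
    reference_map: LandSystemMap
    capability: pd.DataFrame  # (n_systems, n_services)
    demand: pd.Series  # km² per service, target date
    factors: FactorStack
    suitability: SuitabilityModel
    p_loc: np.ndarray  # (n_systems, H, W)
    resistance: np.ndarray
    con: np.ndarray
    config: SimulationConfig
    taxonomy: object | None = None

    @property
    def n_systems(self) -> int:
        return self.initial_map.n


def _p_loc_array(model: SuitabilityModel, factors: FactorStack, n: int) -> np.ndarray:
    return np.stack([predict_suitability(model.fits[j], factors).values for j in range(n)])


def make_study(
    spec: FixtureSpec,
    config: SimulationConfig | None = None,
    interval: int = 1,
    srcc_cutoff: float = 0.9,
    factor_noise: float = 0.5,
) -> Study:
    """Build a complete synthetic study area from a fixture specification.

    Two dates of the micro landscape are generated, aggregated into land
    systems (taxonomy derived from the first date and applied to both),
    capabilities and the target-date demand extracted, driving factors
    generated at the macro resolution, suitability fitted on the first
    date's map, and resistance/allowance estimated from the date pair.

    Driving factors are not pure noise: each factor mixes a smoothed random
    field with one cover type's within-block fraction surface (real driving
    factors carry information about landscape composition — that is why
    suitability regressions on real data reach high AUCs).  The noise share
    is ``factor_noise``.
    """
    micro1, micro2 = make_history_pair(spec)
    fr1 = aggregate_blocks(micro1, spec.block_factor)
    fr2 = aggregate_blocks(micro2, spec.block_factor)
    tax, ls1 = derive_taxonomy(fr1)
    ls2 = apply_taxonomy(tax, fr2)
    cap = capability_matrix(ls1, micro1, spec.block_factor, spec.n_cover_types)
    demand = demand_from_map(micro2, spec.n_cover_types)
    raw_factors, _, _ = make_factor_stack(spec, shape=ls1.grid.values.shape)

    def _std(a: np.ndarray) -> np.ndarray:
        return (a - a.mean()) / a.std()

    layers = []
    for i, g in enumerate(raw_factors.layers):
        signal = fr1.fractions[i % spec.n_cover_types].values
        v = _std(factor_noise * _std(g.values) + _std(signal))
        layers.append(ls1.grid.like(v))
    factors = FactorStack(list(raw_factors.names), layers)
    model = fit_suitability(ls1, factors, srcc_cutoff=srcc_cutoff, interval=interval)
    p_loc = _p_loc_array(model, factors, ls1.n)
    res = estimate_resistance(ls1, ls2)
    con = build_conversion_matrix(ls1, ls2)
    cfg = config or SimulationConfig(rng_seed=spec.seed)
    return Study(ls1, ls2, cap, demand, factors, model, p_loc, res, con, cfg, tax)


def simulate_study(
    study: Study, orders: np.ndarray, seed: int | None = None
) -> TimeStepResult:
    """One allocation time step of a study under a given order matrix."""
    cfg = study.config
    if seed is not None:
        cfg = SimulationConfig(**{**cfg.__dict__, "rng_seed": seed})
    return run_time_step(
        study.initial_map,
        study.p_loc,
        study.resistance,
        np.asarray(orders, dtype=np.int64),
        study.con,
        study.demand.to_numpy(dtype=float),
        cap=study.capability.to_numpy(dtype=float),
        config=cfg,
    )


def evaluate_study(study: Study, result: TimeStepResult) -> dict:
    cm = crosstab(result.map, study.reference_map)
    return {
        "kappa": kappa(cm),
        "total_disagreement": total_disagreement(cm),
        "converged": result.converged,
        "iterations": result.iterations,
    }


# ---------------------------------------------------------------- file-based runs


_REQUIRED_KEYS = ("micro_t1", "micro_t2", "factor_dir")


def validate_config(cfg: dict) -> list[str]:
    """Cross-check a run configuration; returns the complete list of problems."""
    errors = []
    for key in _REQUIRED_KEYS:
        if key not in cfg:
            errors.append(f"missing config key {key!r}")
    for key in ("micro_t1", "micro_t2"):
        path = cfg.get(key)
        if path and not os.path.exists(path):
            errors.append(f"{key}: file not found: {path}")
    fdir = cfg.get("factor_dir")
    if fdir:
        if not os.path.isdir(fdir):
            errors.append(f"factor_dir: not a directory: {fdir}")
        elif not [f for f in os.listdir(fdir) if f.endswith(".asc")]:
            errors.append(f"factor_dir: no .asc factor rasters in {fdir}")
    if errors:
        return errors
    try:
        g1 = read_ascii_grid(cfg["micro_t1"], categorical=True)
        g2 = read_ascii_grid(cfg["micro_t2"], categorical=True)
        require_aligned(g1, g2)
    except (OSError, ValueError, AlignmentError) as exc:
        errors.append(f"micro maps: {exc}")
    if fdir:
        layers = {}
        for f in sorted(os.listdir(fdir)):
            if f.endswith(".asc"):
                try:
                    layers[f] = read_ascii_grid(os.path.join(fdir, f))
                except (OSError, ValueError) as exc:
                    errors.append(f"factor {f}: {exc}")
        try:
            require_aligned(*layers.values())
        except AlignmentError as exc:
            errors.append(f"factor alignment: {exc}")
    orders_path = cfg.get("orders")
    if orders_path and not os.path.exists(orders_path):
        errors.append(f"orders: file not found: {orders_path}")
    return errors


def _read_factors(fdir: str) -> FactorStack:
    names, layers = [], []
    for f in sorted(os.listdir(fdir)):
        if f.endswith(".asc"):
            names.append(os.path.splitext(f)[0])
            layers.append(read_ascii_grid(os.path.join(fdir, f)))
    return FactorStack(names, layers)


def run_pipeline(cfg: dict, out_dir: str) -> dict:
    """Run every stage on file inputs and write all artifacts to ``out_dir``.

    Returns the evaluation metrics.  Stages: taxonomy, capability/demand,
    suitability regression, resistance + allowance, conversion orders
    (``orders_method``: adaptive | rank, or a manual ``orders`` CSV path),
    one allocation step, and evaluation against the second date.
    """
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid configuration:\n" + "\n".join(problems))
    os.makedirs(out_dir, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    block_factor = int(cfg.get("block_factor", 33))

    micro1 = read_ascii_grid(cfg["micro_t1"], categorical=True)
    micro2 = read_ascii_grid(cfg["micro_t2"], categorical=True)
    n_cover = int(max(micro1.values.max(), micro2.values.max())) + 1

    fr1 = aggregate_blocks(micro1, block_factor)
    fr2 = aggregate_blocks(micro2, block_factor)
    tax, ls1 = derive_taxonomy(fr1)
    ls2 = apply_taxonomy(tax, fr2)
    write_ascii_grid(ls1.grid, os.path.join(out_dir, "landsystems_t1.asc"))
    write_ascii_grid(ls2.grid, os.path.join(out_dir, "landsystems_t2.asc"))
    tax.to_frame().to_csv(os.path.join(out_dir, "taxonomy.csv"), index=False)

    cap = capability_matrix(ls1, micro1, block_factor, n_cover)
    cap.to_csv(os.path.join(out_dir, "capability.csv"))
    demand = demand_from_map(micro2, n_cover)
    pd.DataFrame([demand.values], columns=demand.index, index=pd.Index([1], name="step")).to_csv(
        os.path.join(out_dir, "demand.csv")
    )

    raw = _read_factors(cfg["factor_dir"])
    factors = FactorStack(list(raw.names), [ls1.grid.like(g.values) for g in raw.layers])
    model = fit_suitability(
        ls1,
        factors,
        srcc_cutoff=float(cfg.get("srcc_cutoff", 0.9)),
        interval=int(cfg.get("interval", 1)),
    )
    model.to_frame(ls1.legend).to_csv(os.path.join(out_dir, "suitability.csv"), index=False)
    p_loc = _p_loc_array(model, factors, ls1.n)

    res = estimate_resistance(ls1, ls2)
    con = build_conversion_matrix(ls1, ls2, float(cfg.get("conversion_threshold_pct", 1.0)))
    names = [ls1.legend[j] for j in range(ls1.n)]
    pd.DataFrame({"land_system": names, "resistance": res}).to_csv(
        os.path.join(out_dir, "resistance.csv"), index=False
    )
    pd.DataFrame(con, index=names, columns=names).to_csv(os.path.join(out_dir, "allowance.csv"))

    method = cfg.get("orders_method", "adaptive")
    if cfg.get("orders"):
        orders_df = read_table(cfg["orders"], "orders", ls1.legend)
    elif method == "adaptive":
        orders_df = derive_orders(cap, float(cfg.get("gvf_threshold", 0.8)))
    elif method == "rank":
        orders_df = benchmark_orders(cap)
    else:
        raise ValueError(f"unknown orders_method {method!r}")
    orders_df.to_csv(os.path.join(out_dir, "orders.csv"))

    sim_cfg = SimulationConfig(
        rng_seed=seed, max_iterations=int(cfg.get("max_iterations", 20_000))
    )
    study = Study(ls1, ls2, cap, demand, factors, model, p_loc, res, con, sim_cfg, tax)
    result = simulate_study(study, orders_df.to_numpy(dtype=np.int64))
    write_ascii_grid(result.map.grid, os.path.join(out_dir, "simulated.asc"))
    result.trace.to_csv(os.path.join(out_dir, "trace.csv"), index=False)

    metrics = evaluate_study(study, result)
    pd.DataFrame([metrics]).to_csv(os.path.join(out_dir, "metrics.csv"), index=False)
    cfg_text = yaml.safe_dump(cfg, sort_keys=True)
    provenance = {
        "version": __version__,
        "seed": seed,
        "orders_method": "manual" if cfg.get("orders") else method,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "config": cfg,
        "metrics": metrics,
    }
    with open(os.path.join(out_dir, "provenance.json"), "wt", encoding="utf-8") as fh:
        json.dump(provenance, fh, indent=2, default=float)
    return metrics
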