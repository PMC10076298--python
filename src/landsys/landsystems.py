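"""Multifunctional land-system taxonomy from a fine-resolution cover map.

A micro (fine-resolution) categorical raster is aggregated in square blocks
(default 33x33, turning 30 m pixels into 990 m macro pixels).  Each macro
cell is labelled by its dominant cover type at one of three density levels
(low/medium/high), with per-type density thresholds found by natural-breaks
classification of the dominant-cell fractions.  Capabilities S[j,d] — the
amount of service d (area of cover type d, km²/km²) supplied per unit area
of land system j — come from overlaying the macro map back onto the micro
map.  Demand for service d in a year is simply the total micro area of
cover type d that year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import Grid, LandSystemMap
from .orders import best_partition

__all__ = [
    "FractionStack",
    "Taxonomy",
    "aggregate_blocks",
    "derive_taxonomy",
    "apply_taxonomy",
    "capability_matrix",
    "demand_from_map",
    "service_names",
]

_LEVEL_NAMES = ("low", "medium", "high")


def service_names(n_cover_types: int) -> list[str]:
    return [f"cover{d}" for d in range(n_cover_types)]


@dataclass
class FractionStack:
    """Per cover type, a macro-resolution grid of within-block area fractions."""

    cover_types: list[int]
    fractions: list[Grid]  # aligned, values in [0,1]; nodata where block empty
    valid_counts: Grid  # non-nodata micro cells per block
    block_factor: int
    micro_cellsize: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.fractions[0].values.shape

    def array(self) -> np.ndarray:
        """(n_types, H, W) fraction array with NaN where the block is empty."""
        out = np.stack([g.values for g in self.fractions])
        out[:, self.valid_counts.values == 0] = np.nan
        return out


@dataclass
class Taxonomy:
    """Land-system legend: (cover type, density level) -> land-system id.

    ``thresholds[d]`` are the lower bounds of the medium and high density
    classes for cover type d (strictly increasing); a cover type dominating
    too few distinct fraction values collapses to fewer levels and is
    recorded in ``collapsed``.
    """

    mapping: dict[tuple[int, int], int]
    names: dict[int, str]
    thresholds: dict[int, list[float]]
    collapsed: dict[int, int] = field(default_factory=dict)
    degenerate: list[int] = field(default_factory=list)

    @property
    def n_systems(self) -> int:
        return len(self.names)

    def level_of(self, cover: int, fraction: float) -> int:
        th = self.thresholds.get(cover, [])
        return int(np.searchsorted(th, fraction, side="right"))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (cover, level), ls in sorted(self.mapping.items(), key=lambda kv: kv[1]):
            th = self.thresholds.get(cover, [])
            rows.append(
                {
                    "land_system": self.names[ls],
                    "id": ls,
                    "cover_type": cover,
                    "density_level": level,
                    "lower_threshold": th[level - 1] if level > 0 and th else 0.0,
                }
            )
        return pd.DataFrame(rows)


def aggregate_blocks(micro: Grid, factor: int) -> FractionStack:
    """Block-aggregate a categorical micro raster into cover-type fractions.

    The macro cellsize is ``micro.cellsize * factor``.  Trailing partial
    blocks (south and east edges) are dropped, so fractions are exact.
    Fractions are relative to the non-nodata micro cells of each block.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    H, W = micro.values.shape
    mh, mw = H // factor, W // factor
    if mh == 0 or mw == 0:
        raise ValueError("aggregation factor larger than the raster")
    vals = micro.values[: mh * factor, : mw * factor]
    valid = vals != micro.nodata_value
    types = np.unique(vals[valid])
    blocks = vals.reshape(mh, factor, mw, factor)
    validb = valid.reshape(mh, factor, mw, factor)
    denom = validb.sum(axis=(1, 3)).astype(float)
    fracs = []
    for t in types:
        cnt = ((blocks == t) & validb).sum(axis=(1, 3))
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(denom > 0, cnt / np.maximum(denom, 1), -9999.0)
        fracs.append(f)
    # trailing rows dropped at the southern edge: the lower-left corner moves up
    yll = micro.yllcorner + (H - mh * factor) * micro.cellsize
    macro_cs = micro.cellsize * factor

    def mk(a: np.ndarray) -> Grid:
        return Grid(a.astype(float), micro.xllcorner, yll, macro_cs, -9999.0)

    counts = Grid(denom, micro.xllcorner, yll, macro_cs, -9999.0)
    return FractionStack([int(t) for t in types], [mk(f) for f in fracs], counts, factor, micro.cellsize)


def derive_taxonomy(fractions: FractionStack, n_levels: int = 3) -> tuple[Taxonomy, LandSystemMap]:
    """Label each macro cell with a (dominant cover, density level) land system.

    Dominance ties break to the lowest cover-type id.  Density thresholds are
    natural-breaks class bounds (K = ``n_levels``) of the dominant-cell
    fraction values, computed per cover type over its dominant cells only.
    A cover type with fewer distinct fraction values than ``n_levels``
    collapses to that many levels; a type with no variance at all is flagged
    degenerate.
    """
    arr = fractions.array()  # (n_types, H, W), NaN for empty blocks
    valid = ~np.isnan(arr[0])
    dom_idx = np.nanargmax(np.where(np.isnan(arr), -np.inf, arr), axis=0)
    dom_cover = np.asarray(fractions.cover_types)[dom_idx]
    dom_frac = np.take_along_axis(arr, dom_idx[None], axis=0)[0]

    thresholds: dict[int, list[float]] = {}
    collapsed: dict[int, int] = {}
    degenerate: list[int] = []
    levels = np.zeros(dom_cover.shape, dtype=np.int64)
    for cover in fractions.cover_types:
        sel = (dom_cover == cover) & valid
        if not sel.any():
            continue
        vals = dom_frac[sel]
        n_distinct = len(np.unique(vals))
        k = min(n_levels, n_distinct)
        if k < n_levels:
            collapsed[cover] = k
            if k == 1:
                degenerate.append(cover)
        scheme = best_partition(vals, k)
        # lower bound of class x (x >= 1) = smallest value in that class
        th = [float(cls.min()) for cls in scheme.classes[1:]]
        thresholds[cover] = th
        levels[sel] = np.searchsorted(th, vals, side="right")

    # the legend enumerates every (cover, level) combo the thresholds define,
    # not only the observed ones, so later dates classify into the same legend
    mapping: dict[tuple[int, int], int] = {}
    names: dict[int, str] = {}
    combos = [
        (cover, level)
        for cover in sorted(thresholds)
        for level in range(len(thresholds[cover]) + 1)
    ]
    for ls_id, (cover, level) in enumerate(combos):
        mapping[(cover, level)] = ls_id
        lvl = _LEVEL_NAMES[level] if level < 3 else f"level{level}"
        names[ls_id] = f"{lvl}-density cover{cover}"
    tax = Taxonomy(mapping, names, thresholds, collapsed, degenerate)
    if degenerate:
        warnings.warn(
            f"degenerate density classification (no variance) for cover types {degenerate}",
            stacklevel=2,
        )
    return tax, apply_taxonomy(tax, fractions)


def apply_taxonomy(tax: Taxonomy, fractions: FractionStack) -> LandSystemMap:
    """Classify a fraction stack into an existing taxonomy's land systems.

    Cells whose dominant cover type has no entry in the taxonomy (it never
    dominated when the taxonomy was derived) become nodata with a warning.
    """
    arr = fractions.array()
    valid = ~np.isnan(arr[0])
    dom_idx = np.nanargmax(np.where(np.isnan(arr), -np.inf, arr), axis=0)
    dom_cover = np.asarray(fractions.cover_types)[dom_idx]
    dom_frac = np.take_along_axis(arr, dom_idx[None], axis=0)[0]
    ls_vals = np.full(dom_cover.shape, -9999, dtype=np.int64)
    unknown = set()
    for r, c in zip(*np.nonzero(valid)):
        cover = int(dom_cover[r, c])
        if cover not in tax.thresholds:
            unknown.add(cover)
            continue
        level = tax.level_of(cover, dom_frac[r, c])
        ls_vals[r, c] = tax.mapping[(cover, level)]
    if unknown:
        warnings.warn(
            f"cover types unseen at taxonomy derivation mapped to nodata: {sorted(unknown)}",
            stacklevel=2,
        )
    grid = fractions.fractions[0].like(ls_vals)
    grid.nodata_value = -9999
    return LandSystemMap(grid, dict(tax.names))


def capability_matrix(
    ls_map: LandSystemMap, micro: Grid, block_factor: int, n_cover_types: int | None = None
) -> pd.DataFrame:
    """Service capabilities S[j,d] = Λ_{j,d} / Λ_j from the macro/micro overlay.

    Λ_j is the total (non-nodata micro) area of land system j and Λ_{j,d}
    the area of micro cells of cover type d within j's blocks; rows of area
    services therefore sum to 1.  Absent systems get zero rows.
    """
    mh, mw = ls_map.grid.values.shape
    vals = micro.values[: mh * block_factor, : mw * block_factor]
    if vals.shape != (mh * block_factor, mw * block_factor):
        raise ValueError("micro raster does not cover the macro map's blocks")
    valid = vals != micro.nodata_value
    if n_cover_types is None:
        n_cover_types = int(vals[valid].max()) + 1
    blocks = vals.reshape(mh, block_factor, mw, block_factor).transpose(0, 2, 1, 3)
    validb = valid.reshape(mh, block_factor, mw, block_factor).transpose(0, 2, 1, 3)
    ls = ls_map.grid.values
    n = ls_map.n
    counts = np.zeros((n, n_cover_types), dtype=np.int64)
    ls_flat = ls.reshape(-1)
    b_flat = blocks.reshape(mh * mw, -1)
    v_flat = validb.reshape(mh * mw, -1)
    ok = ls_flat != ls_map.grid.nodata_value
    for j in range(n):
        sel = ls_flat == j
        if sel.any():
            cells = b_flat[sel][v_flat[sel]]
            counts[j] = np.bincount(cells, minlength=n_cover_types)
    totals = counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
    absent = [ls_map.legend[j] for j in range(n) if totals[j, 0] == 0]
    if absent:
        warnings.warn(f"land systems with no area get zero capability rows: {absent}", stacklevel=2)
    return pd.DataFrame(
        S, index=[ls_map.legend[j] for j in range(n)], columns=service_names(n_cover_types)
    )


def demand_from_map(micro: Grid, n_cover_types: int | None = None) -> pd.Series:
    """Demand_d = area (km²) of cover type d in the micro map."""
    valid = micro.values != micro.nodata_value
    vals = micro.values[valid]
    if n_cover_types is None:
        n_cover_types = int(vals.max()) + 1
    counts = np.bincount(vals, minlength=n_cover_types)
    return pd.Series(
        counts * micro.cell_area_km2, index=service_names(n_cover_types), name="demand_km2"
    )
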