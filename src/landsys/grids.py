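"""Raster and table I/O.

All rasters are ESRI ASCII grids (.asc); all tables are UTF-8 CSV with a
mandatory header row.  Cell indexing throughout the package is 0-based,
row-major, with row 0 the northernmost row (the ESRI convention).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Grid",
    "LandSystemMap",
    "FactorStack",
    "RegionMask",
    "DemandSeries",
    "GridFormatError",
    "AlignmentError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_table",
    "require_aligned",
]


class GridFormatError(ValueError):
    """Malformed ESRI ASCII grid."""


class AlignmentError(ValueError):
    """Two layers do not share the same georeferencing header."""


_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


@dataclass
class Grid:
    """A single raster layer.

    ``values`` has shape ``(nrows, ncols)``; row 0 is the northernmost row.
    Nodata cells hold ``nodata_value`` exactly (sentinel equality, no
    tolerance, also for floating grids).
    """

    values: np.ndarray
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 1.0
    nodata_value: float = -9999

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise GridFormatError("grid values must be a 2-D array")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is nodata."""
        return self.values == self.nodata_value

    @property
    def cell_area_km2(self) -> float:
        """Area of one cell in km² (cellsize is in metres)."""
        return (self.cellsize / 1000.0) ** 2

    def header(self) -> dict:
        return {
            "ncols": self.ncols,
            "nrows": self.nrows,
            "xllcorner": self.xllcorner,
            "yllcorner": self.yllcorner,
            "cellsize": self.cellsize,
            "nodata_value": self.nodata_value,
        }

    def like(self, values: np.ndarray) -> "Grid":
        """New grid sharing this grid's georeferencing."""
        return Grid(values, self.xllcorner, self.yllcorner, self.cellsize, self.nodata_value)


def require_aligned(*grids: Grid) -> None:
    """Raise AlignmentError unless all grids share shape, cellsize and corners exactly."""
    if not grids:
        return
    ref = grids[0]
    for g in grids[1:]:
        for key in ("nrows", "ncols"):
            if getattr(g, key) != getattr(ref, key):
                raise AlignmentError(
                    f"grids differ in {key}: {getattr(ref, key)} vs {getattr(g, key)}"
                )
        for key in ("cellsize", "xllcorner", "yllcorner"):
            if getattr(g, key) != getattr(ref, key):
                raise AlignmentError(
                    f"grids differ in {key}: {getattr(ref, key)!r} vs {getattr(g, key)!r}"
                )


@dataclass
class LandSystemMap:
    """Categorical raster of land-system (or land-cover) types with a legend.

    Type ids are contiguous integers ``0..n-1``.
    """

    grid: Grid
    legend: dict[int, str]

    def __post_init__(self) -> None:
        vals = self.grid.values
        if not np.issubdtype(vals.dtype, np.integer):
            raise GridFormatError("land-system map must hold integer categories")
        present = np.unique(vals[~self.grid.mask])
        missing = [int(v) for v in present if int(v) not in self.legend]
        if missing:
            raise GridFormatError(f"map values missing from legend: {missing}")
        ids = sorted(self.legend)
        if ids != list(range(len(ids))):
            raise GridFormatError("legend type ids must be 0..n-1")

    @property
    def n(self) -> int:
        return len(self.legend)

    def counts(self) -> np.ndarray:
        """Number of non-nodata cells per type id."""
        valid = self.grid.values[~self.grid.mask]
        return np.bincount(valid, minlength=self.n)


@dataclass
class FactorStack:
    """Aligned stack of continuous driving-factor rasters."""

    names: list[str]
    layers: list[Grid]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.layers):
            raise ValueError("names and layers length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicated factor name")
        require_aligned(*self.layers)

    def __len__(self) -> int:
        return len(self.names)

    def layer(self, name: str) -> Grid:
        try:
            return self.layers[self.names.index(name)]
        except ValueError:
            raise KeyError(f"no factor named {name!r}") from None

    def subset(self, names: list[str]) -> "FactorStack":
        return FactorStack(list(names), [self.layer(n) for n in names])

    def valid_mask(self) -> np.ndarray:
        """Cells valid (non-nodata) in every layer."""
        m = ~self.layers[0].mask
        for g in self.layers[1:]:
            m &= ~g.mask
        return m

    def design_matrix(self, cells: np.ndarray) -> np.ndarray:
        """(len(cells), n_factors) matrix of factor values at flat cell indices."""
        return np.column_stack(
            [g.values.ravel()[cells].astype(float) for g in self.layers]
        )


@dataclass
class RegionMask:
    """Spatial restriction: True cells are frozen, changes never allowed there."""

    grid: Grid

    @property
    def restricted(self) -> np.ndarray:
        return self.grid.values.astype(bool)


@dataclass
class DemandSeries:
    """Demand[d, t] per land-system service, indexed by simulation step."""

    table: pd.DataFrame  # index: step (int), columns: service names

    def __post_init__(self) -> None:
        if (self.table.values < 0).any():
            raise ValueError("negative demand")

    @property
    def services(self) -> list[str]:
        return list(self.table.columns)

    def row(self, step: int) -> np.ndarray:
        if step not in self.table.index:
            raise KeyError(f"no demand row for step {step}")
        return self.table.loc[step].to_numpy(dtype=float)


def read_ascii_grid(path, categorical: bool = False) -> Grid:
    """Read an ESRI ASCII grid.

    Header keys may appear in any order and any case; ``NODATA_value`` is
    optional (default -9999).  ``categorical`` forces integer parsing.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        text = fh.read()
    lines = text.splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for idx, line in enumerate(lines):
        parts = line.split()
        if not parts:
            continue
        key = parts[0].lower()
        if key in _HEADER_KEYS or key == "nodata_value":
            if len(parts) != 2:
                raise GridFormatError(f"malformed header line for key {parts[0]!r}")
            try:
                header[key] = float(parts[1])
            except ValueError:
                raise GridFormatError(f"non-numeric header value for key {parts[0]!r}")
            body_start = idx + 1
        else:
            break
    for key in _HEADER_KEYS:
        if key not in header:
            raise GridFormatError(f"missing header key {key!r}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    nodata = header.get("nodata_value", -9999.0)
    body = "\n".join(lines[body_start:])
    flat = np.loadtxt(io.StringIO(body), dtype=float, ndmin=1).ravel()
    if flat.size != nrows * ncols:
        raise GridFormatError(
            f"expected {nrows * ncols} values ({nrows}x{ncols}), found {flat.size}"
        )
    values = flat.reshape(nrows, ncols)
    if categorical:
        values = values.astype(np.int64)
        nodata = int(nodata)
    return Grid(values, header["xllcorner"], header["yllcorner"], header["cellsize"], nodata)


def write_ascii_grid(grid: Grid, path) -> None:
    """Write a Grid as an ESRI ASCII grid, re-readable to an equal grid.

    Floating values are written with 12 significant digits.
    """
    integral = np.issubdtype(grid.values.dtype, np.integer)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner:.12g}\n")
        fh.write(f"yllcorner {grid.yllcorner:.12g}\n")
        fh.write(f"cellsize {grid.cellsize:.12g}\n")
        if integral:
            fh.write(f"NODATA_value {int(grid.nodata_value)}\n")
            for row in grid.values:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")
        else:
            fh.write(f"NODATA_value {grid.nodata_value:.12g}\n")
            for row in grid.values:
                fh.write(" ".join(f"{v:.12g}" for v in row) + "\n")


_TABLE_KINDS = ("demand", "capability", "orders", "allowance", "resistance", "weights")


def read_table(path, kind: str, legend: dict[int, str] | None = None) -> pd.DataFrame:
    """Read one of the model's CSV tables and validate its domain.

    kinds: demand (rows = steps, first column ``step``), capability
    (rows = land systems, first column names them), orders (integers >= -1),
    allowance (square 0/1 matrix), resistance (columns ``land_system`` and
    ``resistance`` in [0,1]), weights (columns ``service`` and ``weight``;
    a missing file means every weight defaults to 1 — handled by callers).
    """
    if kind not in _TABLE_KINDS:
        raise ValueError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path, encoding="utf-8")
    if kind == "demand":
        if df.columns[0] != "step":
            raise ValueError("demand table must start with a 'step' column")
        df = df.set_index("step")
        if (df.values < 0).any():
            raise ValueError("negative demand")
        return df
    if kind == "weights":
        if list(df.columns) != ["service", "weight"]:
            raise ValueError("weights table needs columns service,weight")
        return df
    if kind == "resistance":
        if list(df.columns) != ["land_system", "resistance"]:
            raise ValueError("resistance table needs columns land_system,resistance")
        if ((df["resistance"] < 0) | (df["resistance"] > 1)).any():
            raise ValueError("resistance outside [0,1]")
        if legend is not None and len(df) != len(legend):
            raise ValueError(
                f"resistance rows ({len(df)}) != legend size ({len(legend)})"
            )
        return df
    # capability / orders / allowance: first column names the rows
    df = df.set_index(df.columns[0])
    if legend is not None and len(df) != len(legend):
        raise ValueError(f"{kind} rows ({len(df)}) != legend size ({len(legend)})")
    if kind == "capability":
        if (df.values < 0).any():
            raise ValueError("negative capability")
    elif kind == "orders":
        vals = df.values
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("non-integer conversion order")
        if (vals < -1).any():
            raise ValueError("conversion order below -1")
        df = df.astype(int)
    elif kind == "allowance":
        if df.shape[0] != df.shape[1]:
            raise ValueError("allowance matrix must be square")
        if not np.isin(df.values, (0, 1)).all():
            raise ValueError("allowance entries must be 0 or 1")
        df = df.astype(int)
    return df


def read_weights(path, services: list[str]) -> np.ndarray:
    """Service weights ω_d; if ``path`` is None or absent, all default to 1."""
    if path is None or not os.path.exists(path):
        return np.ones(len(services))
    df = read_table(path, "weights")
    w = df.set_index("service")["weight"]
    missing = [s for s in services if s not in w.index]
    if missing:
        raise ValueError(f"weights missing for services: {missing}")
    return w.loc[services].to_numpy(dtype=float)
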