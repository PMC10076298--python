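"""Synthetic study-area generators with known ground truth.

Every generator is a pure function of the master seed: each draws from its
own RNG stream, derived from the master seed through a fixed integer key
(`_STREAM_KEYS`), so adding or reordering generators never perturbs the
others.

The fixtures emulate the shape of a fine-resolution (micro) land-cover
product: a categorical raster with spatial autocorrelation, two dates of it
with controllable per-type persistence, and continuous driving-factor
surfaces tied to known logistic coefficients.  They emulate structure only,
not the semantics of any real land-cover legend or geography.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.special import expit

from .grids import FactorStack, Grid

__all__ = [
    "FixtureSpec",
    "make_micro_landscape",
    "make_history_pair",
    "make_factor_stack",
    "draw_presence",
]

# Named sub-stream keys: one per generator.
_STREAM_KEYS = {
    "landscape": 0,
    "history": 1,
    "factors": 2,
    "coeffs": 3,
    "redraw": 4,
    "presence": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAM_KEYS[stream],)))


@dataclass
class FixtureSpec:
    """Parameters of a synthetic study area.

    Defaults mirror the structure of a 30 m land-cover product aggregated in
    33x33 blocks; sizes are desk-scale.  ``persistence`` is the per-type
    probability that a cell keeps its type between the two dates; the
    default grades from 0.95 down to 0.75 across types — landscapes are
    mostly persistent over a decade, but some covers decline while others
    expand, so aggregate demands genuinely shift between the dates.
    """

    seed: int = 0
    micro_shape: tuple[int, int] = (330, 330)
    n_cover_types: int = 4
    autocorrelation_range: int = 8
    block_factor: int = 33
    persistence: np.ndarray | None = None
    n_factors: int = 3
    logit_coeffs: np.ndarray | None = None  # (n_cover_types, n_factors + 1), col 0 = intercept
    cellsize: float = 30.0

    def __post_init__(self) -> None:
        if self.n_cover_types < 2:
            raise ValueError("n_cover_types must be >= 2")
        if self.autocorrelation_range < 0:
            raise ValueError("autocorrelation_range must be >= 0")
        if self.persistence is None:
            self.persistence = np.linspace(0.95, 0.75, self.n_cover_types)
        self.persistence = np.asarray(self.persistence, dtype=float)
        if self.persistence.shape != (self.n_cover_types,):
            raise ValueError("persistence must have one entry per cover type")
        if ((self.persistence < 0) | (self.persistence > 1)).any():
            raise ValueError("persistence outside [0,1]")
        if self.logit_coeffs is None:
            rng = _rng(self.seed, "coeffs")
            b0 = rng.normal(-1.0, 0.5, size=(self.n_cover_types, 1))
            b = rng.normal(0.0, 1.0, size=(self.n_cover_types, self.n_factors))
            self.logit_coeffs = np.hstack([b0, b])
        self.logit_coeffs = np.asarray(self.logit_coeffs, dtype=float)
        if self.logit_coeffs.shape != (self.n_cover_types, self.n_factors + 1):
            raise ValueError(
                "logit_coeffs must have shape (n_cover_types, n_factors + 1)"
            )


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], rng_range: int) -> np.ndarray:
    """Uniform noise smoothed by a square moving window of side 2*range+1."""
    u = rng.random(shape)
    if rng_range > 0:
        u = uniform_filter(u, size=2 * rng_range + 1, mode="reflect")
    return u


def make_micro_landscape(spec: FixtureSpec, shape: tuple[int, int] | None = None) -> Grid:
    """Spatially autocorrelated categorical raster with ``n_cover_types`` types.

    A uniform-noise field is smoothed with a square window of the stated
    autocorrelation range, then split into types at its empirical quantiles,
    so types have (near-)equal areas.  Range 0 gives per-cell independence.
    """
    shape = tuple(shape or spec.micro_shape)
    rng = _rng(spec.seed, "landscape")
    field_ = _smooth_field(rng, shape, spec.autocorrelation_range)
    qs = np.quantile(field_, np.linspace(0, 1, spec.n_cover_types + 1)[1:-1])
    cats = np.searchsorted(qs, field_, side="right").astype(np.int64)
    return Grid(cats, cellsize=spec.cellsize, nodata_value=-9999)


def make_history_pair(spec: FixtureSpec, shape: tuple[int, int] | None = None) -> tuple[Grid, Grid]:
    """Two dates of the micro landscape with per-type persistence.

    The second map equals the first where a per-cell Bernoulli(persistence of
    the cell's type) succeeds; failures are resampled uniformly among the
    other types.
    """
    first = make_micro_landscape(spec, shape)
    rng = _rng(spec.seed, "history")
    cats = first.values
    keep = rng.random(cats.shape) < spec.persistence[cats]
    k = spec.n_cover_types
    draw = rng.integers(0, k - 1, size=cats.shape)
    other = draw + (draw >= cats)  # uniform over the k-1 types != current
    second_vals = np.where(keep, cats, other).astype(np.int64)
    second = first.like(second_vals)
    return first, second


def make_factor_stack(
    spec: FixtureSpec,
    shape: tuple[int, int] | None = None,
    redraw: bool = False,
) -> tuple[FactorStack, list[Grid], Grid | None]:
    """Driving-factor surfaces plus the exact per-type logistic probabilities.

    Factor surfaces are standardized smoothed-noise fields.  For each cover
    type j the returned probability grid is expit(b0_j + sum_f b_{f,j} X_f),
    the closed-form suitability implied by ``spec.logit_coeffs``.  With
    ``redraw=True`` a categorical map is drawn cellwise in proportion to the
    per-type probabilities (normalised per cell).
    """
    shape = tuple(shape or spec.micro_shape)
    rng = _rng(spec.seed, "factors")
    layers = []
    for _ in range(spec.n_factors):
        f = _smooth_field(rng, shape, spec.autocorrelation_range)
        f = (f - f.mean()) / f.std()
        layers.append(Grid(f, cellsize=spec.cellsize, nodata_value=-9999.0))
    names = [f"factor{i}" for i in range(spec.n_factors)]
    stack = FactorStack(names, layers)
    X = np.stack([g.values for g in layers])  # (m, H, W)
    probs = []
    for j in range(spec.n_cover_types):
        b0 = spec.logit_coeffs[j, 0]
        b = spec.logit_coeffs[j, 1:]
        lin = b0 + np.tensordot(b, X, axes=1)
        probs.append(layers[0].like(expit(lin)))
    redrawn = None
    if redraw:
        p = np.stack([g.values for g in probs])
        p = p / p.sum(axis=0)
        u = _rng(spec.seed, "redraw").random(shape)
        cdf = np.cumsum(p, axis=0)
        cats = (u[None, :, :] > cdf).sum(axis=0).astype(np.int64)
        redrawn = Grid(cats, cellsize=spec.cellsize, nodata_value=-9999)
    return stack, probs, redrawn


def draw_presence(prob: Grid, seed: int) -> np.ndarray:
    """Bernoulli presence/absence surface from a probability grid."""
    rng = _rng(seed, "presence")
    return (rng.random(prob.values.shape) < prob.values).astype(np.int64)
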