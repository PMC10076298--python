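"""Local suitability surfaces via logistic regression on driving factors.

For each land system j, presence/absence over the study area is regressed
on the driving-factor stack: ln(P/(1-P)) = β0 + β1 X1 + ... + βm Xm.  The
factor set is first pruned for collinearity (iteratively dropping from the
most correlated pair, by absolute Spearman rank correlation, the member
more correlated with everything else), and the regression uses a regular
spatial subsample (every (interval+1)-th row and column, ≈25% of cells for
interval 1).  Fits are scored by ROC AUC; systems with fewer than 30 cells
in either class are skipped (AUC undefined), which on real data does occur
for rare systems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata, spearmanr

from .grids import FactorStack, Grid, LandSystemMap, RegionMask

__all__ = [
    "LogitFit",
    "SuitabilityModel",
    "spearman_prune",
    "sample_locations",
    "fit_logistic",
    "predict_suitability",
    "roc_auc",
    "fit_suitability",
]

MIN_CLASS_COUNT = 30
_BETA_CAP = 30.0  # |β| cap on the standardized scale under separation
_CLAMP = 1e-12


@dataclass
class LogitFit:
    """One land system's fitted logistic model (original factor scale)."""

    intercept: float
    coef: np.ndarray
    bse: np.ndarray  # (m+1,) standard errors, intercept first
    factor_names: list[str]
    iterations: int
    converged: bool
    auc: float | None = None
    skipped: bool = False
    prevalence: float | None = None  # fallback suitability when skipped

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([[self.intercept], self.coef])


@dataclass
class SuitabilityModel:
    fits: dict[int, LogitFit]  # per land-system id
    factor_names: list[str]

    def to_frame(self, legend: dict[int, str]) -> pd.DataFrame:
        rows = []
        for j, fit in sorted(self.fits.items()):
            row = {"id": j, "land_system": legend[j], "auc": fit.auc}
            row["intercept"] = None if fit.skipped else fit.intercept
            for name, b in zip(fit.factor_names, fit.coef if not fit.skipped else []):
                row[name] = b
            rows.append(row)
        return pd.DataFrame(rows)


def spearman_prune(
    factors: FactorStack, cutoff: float = 0.9, cells: np.ndarray | None = None
) -> list[str]:
    """Collinearity pruning by absolute Spearman rank correlation.

    While any pair exceeds the cutoff, the worst pair (largest |SRCC|, ties
    by name) loses the member with the larger sum of |SRCC| against all
    remaining factors (ties again by name).  Constant factors correlate 0
    with everything, with a warning.  The result is independent of the
    input ordering.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    names = sorted(factors.names)
    if len(names) == 1:
        return list(factors.names)
    if cells is None:
        cells = np.flatnonzero(factors.valid_mask().ravel())
    X = factors.subset(names).design_matrix(cells)
    const = X.std(axis=0) == 0
    if const.any():
        warnings.warn(
            f"constant factors treated as uncorrelated: {[n for n, c in zip(names, const) if c]}",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearmanr(X).statistic
    if X.shape[1] == 2:  # scipy returns a scalar for two variables
        rho = np.array([[1.0, rho], [rho, 1.0]])
    corr = np.abs(np.atleast_2d(np.nan_to_num(rho, nan=0.0)))
    np.fill_diagonal(corr, 0.0)
    alive = list(range(len(names)))
    while len(alive) > 1:
        sub = corr[np.ix_(alive, alive)]
        worst = sub.max()
        if worst <= cutoff:
            break
        a, b = np.argwhere(sub == worst)[0]  # row-major scan = name order (sorted)
        sums = sub.sum(axis=0)
        if sums[a] > sums[b]:
            drop_local = a
        elif sums[b] > sums[a]:
            drop_local = b
        else:
            drop_local = max(a, b)  # tie in sums: drop the later name
        alive.pop(int(drop_local))
    kept = {names[i] for i in alive}
    return [n for n in factors.names if n in kept]


def sample_locations(
    shape: tuple[int, int],
    interval: int = 1,
    mask: RegionMask | None = None,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Flat indices of cells whose row and column are ≡ 0 mod (interval+1).

    Interval 0 keeps every cell; interval 1 keeps ≈25%.  Restricted or
    invalid cells are excluded when given.
    """
    if interval < 0:
        raise ValueError("interval must be >= 0")
    H, W = shape
    keep = np.zeros(shape, dtype=bool)
    keep[:: interval + 1, :: interval + 1] = True
    if mask is not None:
        keep &= ~mask.restricted
    if valid is not None:
        keep &= valid
    return np.flatnonzero(keep.ravel())


def _irls(X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 100):
    """Plain ML logistic fit by iteratively reweighted least squares.

    Returns (beta, cov, iterations, converged); coefficients are capped at
    |β| <= 30 when separation drives them off to infinity.
    """
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        capped = np.clip(beta_new, -_BETA_CAP, _BETA_CAP)
        delta = np.max(np.abs(capped - beta))
        beta = capped
        if delta < tol:
            converged = bool((np.abs(beta_new) <= _BETA_CAP).all())
            break
    mu = expit(X @ beta)
    w = np.maximum(mu * (1 - mu), 1e-10)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return beta, cov, it, converged


def fit_logistic(
    presence: np.ndarray, factors: FactorStack, cells: np.ndarray
) -> LogitFit:
    """Fit one land system's logistic suitability model on sampled cells.

    Factors are standardized internally and the coefficients transformed
    back to the original scale.  If either outcome class has fewer than
    ``MIN_CLASS_COUNT`` cases the fit is skipped (AUC undefined) and the
    observed prevalence is recorded as a constant fallback.
    """
    y = np.asarray(presence, dtype=float).ravel()[cells]
    n1 = int(y.sum())
    n0 = len(y) - n1
    prevalence = y.mean() if len(y) else 0.0
    if min(n0, n1) < MIN_CLASS_COUNT:
        return LogitFit(
            np.nan, np.full(len(factors), np.nan), np.full(len(factors) + 1, np.nan),
            list(factors.names), 0, False, auc=None, skipped=True, prevalence=prevalence,
        )
    Xraw = factors.design_matrix(cells)
    mu_, sd = Xraw.mean(axis=0), Xraw.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = np.column_stack([np.ones(len(y)), (Xraw - mu_) / sd])
    beta_s, cov_s, it, converged = _irls(Xs, y)
    # back-transform: β_f = βs_f/σ_f ; β0 = βs0 - Σ βs_f μ_f/σ_f
    m = len(factors)
    A = np.zeros((m + 1, m + 1))
    A[0, 0] = 1.0
    A[0, 1:] = -mu_ / sd
    A[np.arange(1, m + 1), np.arange(1, m + 1)] = 1.0 / sd
    beta = A @ beta_s
    cov = A @ cov_s @ A.T
    scores = expit(Xs @ beta_s)
    auc = roc_auc(y.astype(int), scores)
    return LogitFit(
        float(beta[0]), beta[1:], np.sqrt(np.diag(cov)), list(factors.names),
        it, converged, auc=auc, prevalence=prevalence,
    )


def predict_suitability(fit: LogitFit, factors: FactorStack) -> Grid:
    """P_loc grid: inverse-logit of the linear predictor, clamped to (0,1).

    A skipped fit yields its constant prevalence surface.
    """
    ref = factors.layers[0]
    if fit.skipped:
        p = np.full(ref.values.shape, min(max(fit.prevalence, _CLAMP), 1 - _CLAMP))
        return ref.like(p)
    missing = [n for n in fit.factor_names if n not in factors.names]
    if missing:
        raise KeyError(f"factors missing for prediction: {missing}")
    X = np.stack([factors.layer(n).values for n in fit.factor_names])
    lin = fit.intercept + np.tensordot(fit.coef, X, axes=1)
    return ref.like(np.clip(expit(lin), _CLAMP, 1 - _CLAMP))


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float | None:
    """AUC via the rank (Mann-Whitney) formulation with midrank tie handling.

    Returns None when only one class is present.
    """
    y = np.asarray(labels).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        return None
    r = rankdata(s, method="average")
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def fit_suitability(
    ls_map: LandSystemMap,
    factors: FactorStack,
    srcc_cutoff: float = 0.9,
    interval: int = 1,
    mask: RegionMask | None = None,
) -> SuitabilityModel:
    """Full suitability stage: prune, sample, fit one model per land system."""
    valid = (~ls_map.grid.mask) & factors.valid_mask()
    cells = sample_locations(ls_map.grid.values.shape, interval, mask, valid)
    kept = spearman_prune(factors, srcc_cutoff, cells)
    sub = factors.subset(kept)
    fits: dict[int, LogitFit] = {}
    for j in range(ls_map.n):
        presence = (ls_map.grid.values == j).astype(np.int64)
        fits[j] = fit_logistic(presence, sub, cells)
        if fits[j].skipped:
            warnings.warn(
                f"land system {ls_map.legend[j]!r}: too few cases, regression skipped",
                stacklevel=2,
            )
    return SuitabilityModel(fits, kept)
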