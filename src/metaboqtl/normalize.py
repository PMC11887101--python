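"""Box-Cox normalization and covariate residualization of metabolite traits.

Each trait y (a metabolite concentration or a concentration ratio) is
power-transformed with the Box-Cox family,

    y(λ) = (y^λ − 1)/λ   for λ ≠ 0,    y(0) = log y,

with λ chosen by maximum profile likelihood of a linear regression of the
transformed trait on the fixed covariates (intercept, carcass weight, sex,
collection-date dummies, optionally breed). The search is a grid of 3001
values on [−3, 3]. Residuals e = y(λ) − ŷ from the covariate fit are the
traits carried into association and network analyses. For network
construction a single λ shared by the most metabolites (judged by the 95%
profile-likelihood intervals) replaces the per-trait λ.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import MetaboliteMatrix

__all__ = [
    "BoxCoxFit",
    "NormalizedMatrix",
    "RatioSet",
    "boxcox_transform",
    "boxcox_fit",
    "residualize",
    "select_common_lambda",
    "build_ratios",
    "normalize_matrix",
]

LAMBDA_GRID = np.linspace(-3.0, 3.0, 3001)
# 95% profile-likelihood cutoff: chi2_1(0.95)/2
CI_DROP = 1.9207


@dataclass
class BoxCoxFit:
    lam: float
    grid: np.ndarray
    grid_loglik: np.ndarray
    ci95: tuple[float, float]
    covariate_betas: pd.Series

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo - 1e-12 <= self.lam <= hi + 1e-12):
            raise ValueError("lambda must lie inside its own 95% interval")


@dataclass
class NormalizedMatrix:
    residuals: pd.DataFrame  # samples × traits
    fitted: pd.DataFrame
    lam_by_trait: pd.Series
    mode: str  # "per-trait" | "common-lambda"


@dataclass
class RatioSet:
    pairs: list  # [(a, b), ...] canonical order (input column order)
    values: pd.DataFrame  # samples × ratios, column "a/b"

    def __len__(self) -> int:
        return len(self.pairs)


def boxcox_transform(y: np.ndarray, lam: float) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if lam == 0.0:
        return np.log(y)
    return (np.power(y, lam) - 1.0) / lam


def _design(covariates) -> pd.DataFrame:
    if hasattr(covariates, "design_matrix"):
        return covariates.design_matrix()
    X = pd.DataFrame(covariates).astype(float)
    if "intercept" not in X.columns:
        X.insert(0, "intercept", 1.0)
    return X


def _qr_full_rank(X: pd.DataFrame) -> np.ndarray:
    Xv = X.to_numpy(dtype=float)
    q, r = np.linalg.qr(Xv)
    diag = np.abs(np.diag(r))
    tol = max(Xv.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = np.where(diag <= tol)[0]
    if bad.size:
        raise ValueError(f"design matrix rank deficient: column {X.columns[bad[0]]!r} is collinear")
    return q


def boxcox_fit(
    y: np.ndarray, covariates, grid: Optional[np.ndarray] = None
) -> BoxCoxFit:
    """Profile-likelihood grid search for the Box-Cox λ within a covariate
    regression.

    The profile log-likelihood at λ is
    −n/2·log(RSS(λ)/n) + (λ−1)·Σ log y, the second term being the Jacobian
    of the transform. The 95% interval collects grid values within 1.92
    log-likelihood units of the maximum.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    X = _design(covariates)
    if len(X) != len(y):
        raise ValueError("covariates and trait length differ")
    Q = _qr_full_rank(X)
    grid = LAMBDA_GRID if grid is None else np.asarray(grid, dtype=float)
    n = len(y)
    logy = np.log(y)
    sum_logy = logy.sum()

    # y^lam for the whole grid at once: exp(outer(log y, lam))
    P = np.exp(np.outer(logy, grid))
    nz = grid != 0.0
    Z = np.empty_like(P)
    Z[:, nz] = (P[:, nz] - 1.0) / grid[nz]
    if (~nz).any():
        Z[:, ~nz] = logy[:, None]

    rss = np.einsum("ij,ij->j", Z, Z) - np.einsum("ij,ij->j", Q.T @ Z, Q.T @ Z)
    rss = np.maximum(rss, np.finfo(float).tiny)
    loglik = -0.5 * n * np.log(rss / n) + (grid - 1.0) * sum_logy

    best = int(np.argmax(loglik))
    lam = float(grid[best])
    inside = loglik >= loglik[best] - CI_DROP
    ci = (float(grid[inside].min()), float(grid[inside].max()))

    z = Z[:, best]
    coefs, *_ = np.linalg.lstsq(X.to_numpy(dtype=float), z, rcond=None)
    betas = pd.Series(coefs, index=X.columns)
    return BoxCoxFit(lam=lam, grid=grid, grid_loglik=loglik, ci95=ci, covariate_betas=betas)


def residualize(y_transformed: np.ndarray, covariates) -> np.ndarray:
    """Least-squares residuals e = y − ŷ of the covariate regression.

    The design always carries an intercept, so residuals sum to ~0 and are
    orthogonal to every covariate column.
    """
    y = np.asarray(y_transformed, dtype=float)
    X = _design(covariates)
    Q = _qr_full_rank(X)
    return y - Q @ (Q.T @ y)


def select_common_lambda(fits: Sequence[BoxCoxFit]) -> float:
    """The grid λ covered by the largest number of per-trait 95% intervals;
    ties resolved toward the median of the per-trait MLEs."""
    fits = list(fits)
    if not fits:
        raise ValueError("need at least one fit")
    grid = fits[0].grid
    coverage = np.zeros(len(grid), dtype=int)
    for f in fits:
        lo, hi = f.ci95
        coverage += (grid >= lo - 1e-12) & (grid <= hi + 1e-12)
    best = coverage.max()
    candidates = grid[coverage == best]
    med = float(np.median([f.lam for f in fits]))
    return float(candidates[np.argmin(np.abs(candidates - med))])


def build_ratios(matrix: MetaboliteMatrix) -> RatioSet:
    """All m(m−1)/2 pairwise concentration ratios a/b on the raw (imputed)
    scale, pairs in input column order."""
    vals = matrix.values
    mets = list(vals.columns)
    if len(mets) < 2:
        raise ValueError("need at least 2 metabolites to form ratios")
    arr = vals.to_numpy(dtype=float)
    if np.any(arr == 0):
        raise ValueError("zero concentrations present; run imputation first")
    pairs = list(itertools.combinations(range(len(mets)), 2))
    out = arr[:, [a for a, _ in pairs]] / arr[:, [b for _, b in pairs]]
    names = [f"{mets[a]}/{mets[b]}" for a, b in pairs]
    return RatioSet(
        pairs=[(mets[a], mets[b]) for a, b in pairs],
        values=pd.DataFrame(out, index=vals.index, columns=names),
    )


def normalize_matrix(
    matrix_or_values,
    covariates,
    mode: str = "per-trait",
    common_lambda: Optional[float] = None,
) -> NormalizedMatrix:
    """Box-Cox + residualize every trait column.

    ``mode='per-trait'`` fits λ per trait; ``mode='common-lambda'`` uses a
    single λ (computed via :func:`select_common_lambda` when not supplied).
    """
    vals = matrix_or_values.values if hasattr(matrix_or_values, "values") and not isinstance(
        matrix_or_values, pd.DataFrame
    ) else pd.DataFrame(matrix_or_values)
    X = _design(covariates)

    fits = {trait: boxcox_fit(vals[trait].to_numpy(), X) for trait in vals.columns}
    if mode == "common-lambda":
        lam_common = (
            select_common_lambda(list(fits.values())) if common_lambda is None else common_lambda
        )
        lam_by_trait = pd.Series(lam_common, index=vals.columns, dtype=float)
    elif mode == "per-trait":
        lam_by_trait = pd.Series({t: f.lam for t, f in fits.items()})
    else:
        raise ValueError(f"unknown mode {mode!r}")

    resid = {}
    fitted = {}
    for trait in vals.columns:
        z = boxcox_transform(vals[trait].to_numpy(), float(lam_by_trait[trait]))
        e = residualize(z, X)
        resid[trait] = e
        fitted[trait] = z - e
    return NormalizedMatrix(
        residuals=pd.DataFrame(resid, index=vals.index),
        fitted=pd.DataFrame(fitted, index=vals.index),
        lam_by_trait=lam_by_trait,
        mode=mode,
    )
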