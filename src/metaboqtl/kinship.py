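"""Relationship matrices and REML variance components.

Two kinships drive the mixed models: the pedigree additive (numerator)
relationship matrix A built by the tabular method, and the centered genomic
relationship matrix K = Wc·Wcᵀ/p (Wc the column-centered dosage matrix, p
the SNP count). Heritability h² = σ²_g/(σ²_g+σ²_e) is estimated by REML for
the model y = μ + g + e, g ~ N(0, σ²_g·K), e ~ N(0, σ²_e·I), via a single
eigendecomposition of K and one-dimensional optimization of the variance
ratio δ = σ²_e/σ²_g on log δ ∈ [−10, 10].
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .datamodel import GenotypeMatrix, Pedigree, RelationshipMatrix

__all__ = [
    "VarianceComponents",
    "additive_relationship_from_pedigree",
    "centered_grm",
    "reml_fit",
    "restricted_loglik",
]


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    h2: float
    se_h2: float
    loglik: float
    flag: str = ""  # "", "boundary", "flat-likelihood"


def additive_relationship_from_pedigree(
    pedigree: Pedigree, max_generations: int = 4
) -> RelationshipMatrix:
    """Tabular-method numerator relationship matrix.

    A_ii = 1 + F_i with F_i half the parents' relationship; A_ij averages
    the relationships of j's parents with i. Ancestors deeper than
    ``max_generations`` above the youngest generation are treated as
    founders (their parents dropped).
    """
    recs = pedigree.records
    ids = list(recs["individual"])
    idx = {ind: k for k, ind in enumerate(ids)}
    gen = dict(zip(recs["individual"], recs["generation"]))
    max_gen = max(gen.values()) if gen else 0
    cutoff = max_gen - max_generations

    n = len(ids)
    A = np.zeros((n, n))
    parents = {}
    for _, row in recs.iterrows():
        ind = row["individual"]
        if gen[ind] <= cutoff:
            parents[ind] = (None, None)
        else:
            parents[ind] = (
                idx.get(row["sire"]) if row["sire"] is not None else None,
                idx.get(row["dam"]) if row["dam"] is not None else None,
            )

    for j, ind in enumerate(ids):  # topological order
        s, d = parents[ind]
        if s is not None and d is not None:
            A[j, j] = 1.0 + 0.5 * A[s, d]
        else:
            A[j, j] = 1.0
        for i in range(j):
            val = 0.0
            if s is not None:
                val += 0.5 * A[i, s]
            if d is not None:
                val += 0.5 * A[i, d]
            A[i, j] = A[j, i] = val
    return RelationshipMatrix(kind="pedigree_A", matrix=A, sample_ids=ids)


def centered_grm(genotypes: GenotypeMatrix, form: str = "centered") -> RelationshipMatrix:
    """Genomic relationship matrix from 0/1/2 dosages.

    ``centered``: K = Wc·Wcᵀ/p (each SNP column mean-centered, divide by SNP
    count). ``standardized``: columns additionally scaled by their standard
    deviation before the same product. Missing dosages are mean-imputed per
    SNP inside this computation only.
    """
    X = genotypes.imputed_dosages()
    keep = X.std(axis=0) > 0
    if not keep.any():
        raise ValueError("all SNPs monomorphic: GRM undefined")
    Wc = X[:, keep] - X[:, keep].mean(axis=0)
    if form == "standardized":
        Wc = Wc / Wc.std(axis=0)
    elif form != "centered":
        raise ValueError(f"unknown GRM form {form!r}")
    p = Wc.shape[1]
    K = Wc @ Wc.T / p
    return RelationshipMatrix(kind="genomic_K", matrix=K, sample_ids=genotypes.sample_ids)


def restricted_loglik(delta: float, d: np.ndarray, Xt: np.ndarray, yt: np.ndarray) -> tuple[float, float]:
    """Profile restricted log-likelihood at variance ratio δ = σ²_e/σ²_g,
    in the eigenbasis of K (eigenvalues ``d``, rotated design ``Xt`` and
    trait ``yt``). Returns (logL_R, σ̂²_g)."""
    n, c = Xt.shape
    h = d + delta
    if np.any(h <= 0):
        return -np.inf, np.nan
    w = 1.0 / h
    XtWX = Xt.T @ (Xt * w[:, None])
    XtWy = Xt.T @ (yt * w)
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan
    r = yt - Xt @ beta
    ypy = float(np.sum(r * r * w))
    if ypy <= 0:
        return -np.inf, np.nan
    sigma_g2 = ypy / (n - c)
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf, np.nan
    ll = -0.5 * (
        (n - c) * np.log(2.0 * np.pi * sigma_g2)
        + np.sum(np.log(h))
        + logdet_XtWX
        + (n - c)
    )
    return float(ll), float(sigma_g2)


def reml_fit(
    e_residuals: np.ndarray,
    K,
    X: Optional[np.ndarray] = None,
    eig: Optional[tuple] = None,
    log_delta_bounds: tuple = (-10.0, 10.0),
) -> VarianceComponents:
    """REML variance components for y = Xα + g + e (default X = intercept).

    The optimum of δ is located by a coarse grid then refined by Brent
    search on log δ. Estimates pinned at the search boundary are flagged
    ``boundary`` (h² clamped into [0, 1]); an identification failure (e.g.
    K ∝ I, likelihood flat in δ) is flagged ``flat-likelihood``.
    """
    y = np.asarray(e_residuals, dtype=float)
    n = len(y)
    Kmat = K.matrix if isinstance(K, RelationshipMatrix) else np.asarray(K, dtype=float)
    if Kmat.shape != (n, n):
        raise ValueError("K dimension does not match trait length")
    if X is None:
        X = np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T

    if eig is None:
        d, U = np.linalg.eigh(Kmat)
    else:
        d, U = eig
    if d.min() < -1e-6 * max(1.0, d.max()):
        raise ValueError("K is not positive semidefinite")
    d = np.maximum(d, 0.0)
    yt, Xt = U.T @ y, U.T @ X

    lo, hi = log_delta_bounds
    grid = np.linspace(lo, hi, 41)
    lls = np.array([restricted_loglik(np.exp(g), d, Xt, yt)[0] for g in grid])
    flag = ""
    if lls.max() - lls.min() < 1e-6:
        flag = "flat-likelihood"
        best = np.exp(grid[len(grid) // 2])
    else:
        i = int(np.argmax(lls))
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda g: -restricted_loglik(np.exp(g), d, Xt, yt)[0],
            bounds=(a, b),
            method="bounded",
            options={"xatol": 1e-8},
        )
        best = float(np.exp(res.x))
        if res.x <= lo + 0.05 or res.x >= hi - 0.05:
            flag = "boundary"

    ll, sigma_g2 = restricted_loglik(best, d, Xt, yt)
    sigma_e2 = best * sigma_g2
    # population-average genetic variance is σ²_g·mean(diag K); h² uses it
    # so the estimate is invariant to the overall scaling of K
    kbar = float(np.mean(np.diag(Kmat)))
    h2 = kbar / (kbar + best)
    if flag == "boundary":
        h2 = min(max(h2, 0.0), 1.0)
        if h2 < 1e-4:
            h2, sigma_g2 = 0.0, 0.0

    # SE from the curvature of the profile REML in h2 (numerical)
    se_h2 = np.nan
    if flag == "":
        eps = 1e-4
        def ll_of_h2(h):
            h = min(max(h, 1e-9), 1 - 1e-9)
            return restricted_loglik(kbar * (1.0 - h) / h, d, Xt, yt)[0]
        f0, fp, fm = ll_of_h2(h2), ll_of_h2(h2 + eps), ll_of_h2(h2 - eps)
        curv = (fp - 2 * f0 + fm) / eps**2
        if curv < 0:
            se_h2 = float(1.0 / np.sqrt(-curv))
    return VarianceComponents(
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_e2),
        h2=float(h2),
        se_h2=se_h2,
        loglik=float(ll),
        flag=flag,
    )
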