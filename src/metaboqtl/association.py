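"""Linear-mixed-model association scans and downstream mQTL calling.

Per trait (a normalized metabolite residual or ratio residual) and SNP x,
the model is y = Wα + xβ + g + e with g ~ N(0, σ²_g·K) and e ~ N(0, σ²_e·I);
H0: β = 0 is tested with a Wald statistic from generalized least squares
under V = σ²_g·K + σ²_e·I. Variance components are re-optimized per SNP
("exact" mode) or fixed at the null-model fit ("null_vc"). Downstream:
per-SNP variance explained (PVE), LD-based effective test counts, the
p-gain statistic for ratios, sample-size-weighted Z-score meta-analysis,
and 1 Mb / 0.5 Mb region merging with ±500 kb gene annotation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GeneTable, GenotypeMatrix, RelationshipMatrix
from .kinship import reml_fit, restricted_loglik

__all__ = [
    "LmmNull",
    "MetaResult",
    "MQTLRegion",
    "SignificanceThresholds",
    "fit_null",
    "lmm_scan",
    "pve",
    "effective_tests_ld",
    "pgain_scan",
    "meta_weighted_z",
    "significance_thresholds",
    "call_mqtl_regions",
    "annotate_regions",
    "ratio_profile_2d",
]


@dataclass
class LmmNull:
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    delta: float  # σ²_e/σ²_g at the null fit
    sigma_g2: float
    sigma_e2: float
    y_rotated: np.ndarray
    alpha: np.ndarray  # covariate effects for W (intercept-only default)
    flag: str = ""


def _eig_K(K) -> tuple[np.ndarray, np.ndarray]:
    Kmat = K.matrix if isinstance(K, RelationshipMatrix) else np.asarray(K, dtype=float)
    d, U = np.linalg.eigh(Kmat)
    if d.min() < -1e-8 * max(1.0, abs(d.max())):
        raise ValueError("K must be positive semidefinite")
    return np.maximum(d, 0.0), U


def fit_null(e_residuals: np.ndarray, K) -> LmmNull:
    """Null model y = Wα + g + e (W = intercept): REML variance components
    and the eigenrotation reused across the scan."""
    y = np.asarray(e_residuals, dtype=float)
    d, U = _eig_K(K)
    vc = reml_fit(y, K if isinstance(K, RelationshipMatrix) else np.asarray(K), eig=(d, U))
    # at the σ²_g = 0 boundary keep the finite search-boundary δ (e^10):
    # GLS weights then collapse to the OLS limit without infinities
    delta = vc.sigma_e2 / vc.sigma_g2 if vc.sigma_g2 > 0 else math.exp(10.0)
    yt = U.T @ y
    ones_t = U.T @ np.ones(len(y))
    w = 1.0 / (d + delta) if np.isfinite(delta) else np.ones(len(d))
    alpha = np.array([float(np.sum(w * ones_t * yt) / np.sum(w * ones_t**2))])
    return LmmNull(
        eigenvalues=d, eigenvectors=U, delta=float(delta),
        sigma_g2=vc.sigma_g2, sigma_e2=vc.sigma_e2,
        y_rotated=yt, alpha=alpha, flag=vc.flag,
    )


def _gls_stats(yt, ones_t, xt, w, n):
    """GLS β̂, se, Wald P for design [1, x] with diagonal weights w in the
    eigenbasis; residual variance REML-estimated at n−2 dof."""
    a11 = float(np.sum(w * ones_t * ones_t))
    a12 = float(np.sum(w * ones_t * xt))
    a22 = float(np.sum(w * xt * xt))
    b1 = float(np.sum(w * ones_t * yt))
    b2 = float(np.sum(w * xt * yt))
    det = a11 * a22 - a12 * a12
    if det <= 0:
        return np.nan, np.nan, np.nan
    beta = (a11 * b2 - a12 * b1) / det
    alpha = (a22 * b1 - a12 * b2) / det
    rss = float(np.sum(w * yt * yt)) - alpha * b1 - beta * b2
    sigma2 = max(rss, 0.0) / (n - 2)
    se = math.sqrt(sigma2 * a11 / det)
    if se == 0:
        return beta, se, np.nan
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return beta, se, max(p, np.finfo(float).tiny)


def lmm_scan(
    e_residuals: np.ndarray,
    genotypes: GenotypeMatrix,
    K,
    mode: str = "exact",
    trait_id: str = "trait",
    null: Optional[LmmNull] = None,
) -> pd.DataFrame:
    """Per-SNP mixed-model association scan.

    ``exact`` re-optimizes δ = σ²_e/σ²_g per SNP (REML with W = [1, x]);
    ``null_vc`` keeps δ from the null fit. Monomorphic SNPs yield missing
    statistics with a flag. Returns a DataFrame with snp_id, chromosome,
    position_bp, maf, beta, se, p_wald, n, pve and flag columns.
    """
    if mode not in ("exact", "null_vc"):
        raise ValueError(f"unknown mode {mode!r}")
    y = np.asarray(e_residuals, dtype=float)
    n = len(y)
    if genotypes.n_samples != n:
        raise ValueError("residuals and genotypes are not sample-aligned")
    if null is None:
        null = fit_null(y, K)
    d, U = null.eigenvalues, null.eigenvectors
    yt = null.y_rotated
    ones_t = U.T @ np.ones(n)

    X = genotypes.imputed_dosages()
    Xt = U.T @ X
    snp_tab = genotypes.snp_map.table

    w_null = 1.0 / (d + null.delta) if np.isfinite(null.delta) else None

    rows = []
    for j, snp_id in enumerate(snp_tab["snp_id"]):
        xt = Xt[:, j]
        maf = float(snp_tab["maf"].iloc[j])
        if X[:, j].std() == 0:
            rows.append((snp_id, np.nan, np.nan, np.nan, np.nan, "monomorphic"))
            continue
        if mode == "null_vc":
            w = w_null if w_null is not None else 1.0 / np.maximum(d, 1e-12)
            beta, se, p = _gls_stats(yt, ones_t, xt, w, n)
        else:
            Xdes = np.column_stack([ones_t, xt])
            vc = _reml_delta(d, Xdes, yt)
            w = 1.0 / (d + vc)
            beta, se, p = _gls_stats(yt, ones_t, xt, w, n)
        pv = pve(beta, se, maf, n) if se and se > 0 and not np.isnan(se) else np.nan
        rows.append((snp_id, beta, se, p, pv, ""))

    out = pd.DataFrame(rows, columns=["snp_id", "beta", "se", "p_wald", "pve", "flag"])
    out.insert(1, "chromosome", snp_tab["chromosome"].to_numpy())
    out.insert(2, "position_bp", snp_tab["position_bp"].to_numpy())
    out.insert(3, "maf", snp_tab["maf"].to_numpy())
    out["n"] = n
    out["trait_id"] = trait_id
    return out


def _reml_delta(d, Xt, yt, log_bounds=(-10.0, 10.0)) -> float:
    """Per-SNP REML re-optimization of δ in the eigenbasis."""
    from scipy.optimize import minimize_scalar

    grid = np.linspace(*log_bounds, 21)
    lls = [restricted_loglik(math.exp(g), d, Xt, yt)[0] for g in grid]
    i = int(np.argmax(lls))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda g: -restricted_loglik(math.exp(g), d, Xt, yt)[0],
        bounds=(a, b), method="bounded", options={"xatol": 1e-6},
    )
    return float(math.exp(res.x))


def pve(beta: float, se: float, maf: float, n: int) -> float:
    """Per-SNP variance explained:
    PVE = 2β̂²·maf(1−maf) / (2β̂²·maf(1−maf) + se²·2n·maf(1−maf))."""
    if se is None or se <= 0 or np.isnan(se):
        raise ValueError("se must be > 0")
    if not (0 < maf <= 0.5):
        raise ValueError("maf must lie in (0, 0.5]")
    if n < 1:
        raise ValueError("n must be >= 1")
    num = 2.0 * beta * beta * maf * (1.0 - maf)
    den = num + se * se * 2.0 * n * maf * (1.0 - maf)
    return float(min(max(num / den, 0.0), 1.0))


def effective_tests_ld(
    genotypes: GenotypeMatrix,
    r2_threshold: float = 0.25,
    window: int = 100,
    step: int = 5,
) -> int:
    """Greedy windowed LD pruning; the survivor count is the effective
    number of independent tests.

    Within each sliding window (per chromosome, position order), for every
    SNP pair with r² ≥ threshold the lower-MAF SNP is removed (tie: the one
    at the larger position). r² is the squared Pearson correlation of
    mean-imputed dosages (composite LD).
    """
    X = genotypes.imputed_dosages()
    tab = genotypes.snp_map.table
    alive = np.ones(len(tab), dtype=bool)
    alive[X.std(axis=0) == 0] = False  # monomorphic: no test

    for chrom, block in tab.groupby("chromosome", sort=False):
        order = block.sort_values("position_bp", kind="mergesort").index.to_numpy()
        for start in range(0, len(order), step):
            idx = [j for j in order[start:start + window] if alive[j]]
            if len(idx) < 2:
                continue
            sub = X[:, idx]
            C = np.corrcoef(sub, rowvar=False)
            r2 = C * C
            for a in range(len(idx)):
                if not alive[idx[a]]:
                    continue
                for b in range(a + 1, len(idx)):
                    if not alive[idx[b]]:
                        continue
                    if r2[a, b] >= r2_threshold:
                        ja, jb = idx[a], idx[b]
                        maf_a, maf_b = tab["maf"].iloc[ja], tab["maf"].iloc[jb]
                        if maf_a > maf_b:
                            drop = jb
                        elif maf_b > maf_a:
                            drop = ja
                        else:
                            pos_a, pos_b = tab["position_bp"].iloc[ja], tab["position_bp"].iloc[jb]
                            drop = ja if pos_a > pos_b else jb
                        alive[drop] = False
                        if drop == ja:
                            break
    return int(alive.sum())


@dataclass
class SignificanceThresholds:
    alpha: float
    m_eff: int
    threshold_single: float
    m_shared: Optional[int] = None
    threshold_meta_bonferroni: Optional[float] = None
    n_ratios: Optional[int] = None
    pgain_critical: Optional[float] = None


def significance_thresholds(
    m_eff: int,
    alpha: float = 0.05,
    m_shared: Optional[int] = None,
    n_ratios: Optional[int] = None,
) -> SignificanceThresholds:
    """LD-based Bonferroni (α/m_eff), plain Bonferroni over shared SNPs for
    meta-analysis, and the p-gain critical level 10 × n_ratios."""
    return SignificanceThresholds(
        alpha=alpha,
        m_eff=m_eff,
        threshold_single=alpha / m_eff,
        m_shared=m_shared,
        threshold_meta_bonferroni=(alpha / m_shared) if m_shared else None,
        n_ratios=n_ratios,
        pgain_critical=(10.0 * n_ratios) if n_ratios else None,
    )


def pgain_scan(
    ratio_assocs: pd.DataFrame,
    single_assocs: pd.DataFrame,
    n_ratios: int,
    single_p_threshold: Optional[float] = None,
    require_single_threshold: bool = True,
) -> pd.DataFrame:
    """p-gain = min(p_a, p_b)/p_ratio per SNP × ratio.

    ``ratio_assocs`` must carry trait_id of the form "a/b"; ``single_assocs``
    the single-metabolite scans of the same SNPs and cohort. A ratio is
    flagged significant when p_gain ≥ 10·n_ratios and (by default) the ratio
    itself passes the single-trait significance threshold.
    """
    critical = 10.0 * n_ratios
    singles = single_assocs.set_index(["snp_id", "trait_id"])["p_wald"]
    rows = []
    for _, r in ratio_assocs.iterrows():
        a, b = str(r["trait_id"]).split("/", 1)
        p_a = float(singles.get((r["snp_id"], a), np.nan))
        p_b = float(singles.get((r["snp_id"], b), np.nan))
        p_ratio = float(r["p_wald"])
        flag = ""
        if p_ratio == 0:
            p_gain = np.inf
            flag = "p_ratio-underflow"
        else:
            p_gain = min(p_a, p_b) / p_ratio
        sig = p_gain >= critical
        if require_single_threshold and single_p_threshold is not None:
            sig = sig and (p_ratio <= single_p_threshold)
        rows.append({
            "snp_id": r["snp_id"], "trait_id": r["trait_id"],
            "p_a": p_a, "p_b": p_b, "p_ratio": p_ratio,
            "p_gain": p_gain, "significant": bool(sig), "flag": flag,
        })
    return pd.DataFrame(rows)


@dataclass
class MetaResult:
    z_meta: float
    p_meta: float
    direction: str  # e.g. "++", "+-"
    per_study: list = field(default_factory=list)  # (z_i, n_i)


def meta_weighted_z(per_study: Sequence[tuple]) -> MetaResult:
    """Sample-size-weighted Z-score meta-analysis.

    Each study contributes (two-sided p, sign of β, N); Z_i = sign·Φ⁻¹(1 −
    p/2), w_i = √N_i, Z_meta = Σw_i·Z_i/√(Σw_i²), p_meta two-sided.
    """
    if len(per_study) < 1:
        raise ValueError("need at least one study")
    zs, ws, signs = [], [], []
    for p, sign, n in per_study:
        if not (0 < p <= 1):
            raise ValueError(f"p must lie in (0, 1], got {p}")
        if n <= 0:
            raise ValueError("study sample size must be positive")
        s = 1.0 if sign >= 0 else -1.0
        zs.append(s * stats.norm.isf(p / 2.0))
        ws.append(math.sqrt(n))
        signs.append("+" if s > 0 else "-")
    zs, ws = np.asarray(zs), np.asarray(ws)
    z_meta = float(np.sum(ws * zs) / math.sqrt(float(np.sum(ws * ws))))
    p_meta = float(max(2.0 * stats.norm.sf(abs(z_meta)), np.finfo(float).tiny))
    return MetaResult(z_meta=z_meta, p_meta=p_meta, direction="".join(signs),
                      per_study=list(zip(zs.tolist(), [w * w for w in ws])))


@dataclass
class MQTLRegion:
    chromosome: str
    start_bp: int
    end_bp: int
    lead_snp: str
    lead_trait: str
    lead_p: float
    members: pd.DataFrame
    contexts: set
    genes: Optional[pd.DataFrame] = None


def _cluster_positions(positions: np.ndarray, gap: float) -> list:
    """Split sorted positions where consecutive gaps reach ``gap``."""
    groups, current = [], [0]
    for k in range(1, len(positions)):
        if positions[k] - positions[k - 1] < gap:
            current.append(k)
        else:
            groups.append(current)
            current = [k]
    groups.append(current)
    return groups


def call_mqtl_regions(
    significant_pairs: pd.DataFrame,
    same_context_gap: int = 1_000_000,
    cross_context_gap: int = 500_000,
) -> list:
    """Merge significant SNP–trait pairs into mQTL regions.

    Within one analysis context (breed/meta, same or different traits of
    that context), significant SNPs on a chromosome belong to one region
    while consecutive positions are < 1 Mb apart. Regions from different
    contexts are then merged when their spans come within 0.5 Mb. The lead
    is the most significant member (min p; members carrying only a p_gain
    are ranked by 1/p_gain). Input order does not matter.

    Required columns: snp_id, trait_id, chromosome, position_bp, context,
    and p (NaN allowed when p_gain given) / optional p_gain.
    """
    df = significant_pairs.copy()
    if "p_gain" not in df.columns:
        df["p_gain"] = np.nan
    if "p" not in df.columns:
        df["p"] = np.nan
    df["_score"] = df["p"].where(df["p"].notna(), 1.0 / df["p_gain"])
    df = df.sort_values(["chromosome", "position_bp", "snp_id", "trait_id"],
                        kind="mergesort").reset_index(drop=True)

    regions = []
    for chrom, chrom_block in df.groupby("chromosome", sort=False):
        clusters = []  # (start, end, frame)
        for ctx, block in chrom_block.groupby("context", sort=False):
            block = block.sort_values("position_bp", kind="mergesort")
            pos = block["position_bp"].to_numpy()
            for grp in _cluster_positions(pos, same_context_gap):
                sub = block.iloc[grp]
                clusters.append([int(sub["position_bp"].min()),
                                 int(sub["position_bp"].max()), sub])
        # transitive cross-context merging of clusters whose spans come
        # within cross_context_gap (overlapping spans always merge)
        clusters.sort(key=lambda c: (c[0], c[1]))
        merged = []
        for c in clusters:
            if merged and c[0] - merged[-1][1] < cross_context_gap:
                merged[-1][1] = max(merged[-1][1], c[1])
                merged[-1][2] = pd.concat([merged[-1][2], c[2]])
            else:
                merged.append(c)
        for start, end, members in merged:
            members = members.sort_values(["_score", "position_bp"], kind="mergesort")
            lead = members.iloc[0]
            regions.append(MQTLRegion(
                chromosome=str(chrom), start_bp=start, end_bp=end,
                lead_snp=str(lead["snp_id"]), lead_trait=str(lead["trait_id"]),
                lead_p=float(lead["_score"]),
                members=members.drop(columns=["_score"]).reset_index(drop=True),
                contexts=set(members["context"]),
            ))
    regions.sort(key=lambda r: (r.chromosome, r.start_bp))
    return regions


def annotate_regions(
    regions: Sequence[MQTLRegion], gene_table: GeneTable, window: int = 500_000
) -> list:
    """Attach genes overlapping [lead − window, lead + window] (closed
    interval), sorted by distance to the lead SNP."""
    gt = gene_table.table
    for region in regions:
        lead_pos = int(
            region.members.set_index("snp_id")["position_bp"].get(region.lead_snp)
        )
        lo, hi = lead_pos - window, lead_pos + window
        hits = gt[(gt["chromosome"].astype(str) == region.chromosome)
                  & (gt["end_bp"] >= lo) & (gt["start_bp"] <= hi)].copy()
        if len(hits):
            dist = np.where(
                (hits["start_bp"] <= lead_pos) & (hits["end_bp"] >= lead_pos), 0,
                np.minimum(np.abs(hits["start_bp"] - lead_pos),
                           np.abs(hits["end_bp"] - lead_pos)),
            )
            hits["distance_bp"] = dist
            hits = hits.sort_values(["distance_bp", "start_bp"], kind="mergesort")
        else:
            hits["distance_bp"] = pd.Series(dtype=int)
        region.genes = hits.reset_index(drop=True)
    return list(regions)


def ratio_profile_2d(snp_id: str, ratio_assocs: pd.DataFrame) -> pd.DataFrame:
    """Symmetric metabolite × metabolite matrix of −log10 p_ratio for one
    SNP (heatmap export of the two-dimensional ratio-association profile)."""
    block = ratio_assocs[ratio_assocs["snp_id"] == snp_id]
    mets = []
    for t in block["trait_id"]:
        for part in str(t).split("/", 1):
            if part not in mets:
                mets.append(part)
    M = pd.DataFrame(0.0, index=mets, columns=mets)
    for _, r in block.iterrows():
        a, b = str(r["trait_id"]).split("/", 1)
        v = -math.log10(max(float(r["p_wald"]), np.finfo(float).tiny))
        M.loc[a, b] = M.loc[b, a] = v
    return M
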