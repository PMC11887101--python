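"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator produces (i) a multi-generation pedigree of litters, (ii)
SNP-chip-style genotypes by gene dropping founder haplotypes that carry
first-order (Markov) linkage disequilibrium, (iii) a metabolome whose latent
traits follow the generative model

    u = μ0 + β_w·w + β_s·s + Σ β_Cj·d_j + Σ x·β_snp + g + ε,
    g ~ N(0, σ²_g·K),   ε rows ~ N(0, Ω⁻¹),

observed through the inverse Box-Cox transform with per-metabolite λ, then
censored (below-LOD zeros) and contaminated (multiplicative sample
outliers), and (iv) the two-genotype × two-Trp-level kynurenine-pathway
cohort of the nutrigenetic design. A ``SimulationTruth`` records every
planted quantity for recovery tests.

The breed presets approximate the study cohorts: ~790 (Large White) and
~290 (Duroc) animals over ≤ 4 pedigree generations with litters of three
sibs, 60k-chip-scale SNP counts, and 169/164 retained metabolites.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    GenotypeMatrix,
    MetaboliteMatrix,
    Pedigree,
    SampleCovariates,
    SnpMap,
    polarize_to_minor,
)
from .io import build_pedigree
from .kp import KP_SPECIES, KPParameters, analytic_steady_state

__all__ = [
    "SimConfig",
    "SimulationTruth",
    "PlantedQTL",
    "simulate_pedigree",
    "simulate_genotypes",
    "make_truth",
    "simulate_metabolome",
    "simulate_ggm_data",
    "simulate_kp_cohort",
    "chain_precision",
]


@dataclass
class SimConfig:
    n_founders: int = 60
    n_generations: int = 2
    litter_size: int = 3
    n_snps: int = 2000
    n_chromosomes: int = 18
    maf_range: tuple = (0.05, 0.5)
    ld_decay_parameter: float = 0.8  # adjacent-SNP latent (copula) correlation
    snp_spacing_bp: int = 40_000
    n_metabolites: int = 20
    zero_rate: float = 0.02
    outlier_rate: float = 0.01
    outlier_factor: float = 3.0
    outlier_met_frac: float = 0.4
    n_plates: int = 4
    n_dates: int = 5
    cov_var_share: float = 0.2  # variance share of fixed covariates in the latent trait
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_founders", "litter_size", "n_snps", "n_chromosomes",
                     "n_metabolites", "n_plates", "n_dates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")

    @classmethod
    def large_white(cls, **kw) -> "SimConfig":
        """~787-animal cohort, 60k-chip scale, 169 metabolites."""
        base = dict(n_founders=97, n_generations=3, litter_size=3,
                    n_snps=45_000, n_metabolites=169)
        base.update(kw)
        return cls(**base)

    @classmethod
    def duroc(cls, **kw) -> "SimConfig":
        """~285-animal cohort, 60k-chip scale, 164 metabolites."""
        base = dict(n_founders=60, n_generations=2, litter_size=3,
                    n_snps=38_000, n_metabolites=164)
        base.update(kw)
        return cls(**base)


@dataclass
class PlantedQTL:
    snp_id: str
    trait_id: str
    beta: float
    expected_pve: float


@dataclass
class SimulationTruth:
    planted_mqtl: list  # of PlantedQTL
    h2_by_metabolite: pd.Series
    lambda_by_metabolite: pd.Series
    precision_matrix: np.ndarray  # Ω, metabolites × metabolites
    covariate_effects: pd.DataFrame  # metabolite × covariate betas (latent scale)
    seed: int

    def __post_init__(self) -> None:
        O = np.asarray(self.precision_matrix, dtype=float)
        if not np.allclose(O, O.T, atol=1e-10):
            raise ValueError("precision matrix must be symmetric")
        if np.linalg.eigvalsh(O).min() <= 0:
            raise ValueError("precision matrix must be positive definite")
        h2 = self.h2_by_metabolite.to_numpy(dtype=float)
        if np.any((h2 < 0) | (h2 > 1)):
            raise ValueError("h2 must lie in [0, 1]")


def _stage_rngs(seed: int, n: int) -> list:
    """Fan the global seed out into independent per-stage generators."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Founder generation plus litters of full sibs; random mating of the
    previous generation, litter size ``config.litter_size``."""
    if config.litter_size < 1:
        raise ValueError("litter_size must be >= 1")
    rng = _stage_rngs(config.seed, 4)[0]
    parents: dict = {}
    sex: dict = {}
    founders = [f"F{k:04d}" for k in range(config.n_founders)]
    for k, ind in enumerate(founders):
        parents[ind] = (None, None)
        sex[ind] = "M" if k % 2 == 0 else "F"
    prev = founders
    for g in range(1, config.n_generations + 1):
        males = [i for i in prev if sex[i] == "M"]
        females = [i for i in prev if sex[i] == "F"]
        rng.shuffle(males)
        rng.shuffle(females)
        children = []
        for lit, (sire, dam) in enumerate(zip(males, females)):
            for c in range(config.litter_size):
                ind = f"G{g}L{lit:03d}C{c}"
                parents[ind] = (sire, dam)
                sex[ind] = "M" if (lit + c) % 2 == 0 else "F"
                children.append(ind)
        prev = children
    return build_pedigree(parents)


def _founder_haplotypes(rng, n_hap: int, freqs: np.ndarray, rho: float) -> np.ndarray:
    """Markov (AR(1) Gaussian copula) haplotypes: adjacent-SNP latent
    correlation ``rho``; marginal allele frequency per SNP preserved."""
    m = len(freqs)
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        eps = rng.standard_normal((n_hap, m - 1))
        s = math.sqrt(max(1.0 - rho * rho, 0.0))
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + s * eps[:, j - 1]
    thresh = stats.norm.ppf(freqs)
    return (z < thresh[None, :]).astype(np.int8)


def _gametes(rng, hap_pair: np.ndarray, n_gametes: int, r: float) -> np.ndarray:
    """Meiosis with recombination: switch parental haplotype with
    probability ``r`` between adjacent SNPs."""
    m = hap_pair.shape[1]
    start = rng.integers(0, 2, size=n_gametes)
    if m > 1 and r > 0:
        switches = (rng.random((n_gametes, m - 1)) < r).astype(np.int64)
        cum = np.concatenate(
            [np.zeros((n_gametes, 1), dtype=np.int64), np.cumsum(switches, axis=1)], axis=1
        )
        choice = (start[:, None] + cum) % 2
    else:
        choice = np.repeat(start[:, None], m, axis=1)
    return hap_pair[choice, np.arange(m)[None, :]]


def simulate_genotypes(pedigree: Pedigree, config: SimConfig) -> GenotypeMatrix:
    """Gene dropping: founder haplotypes with first-order LD, Mendelian
    transmission with ~1 expected crossover per chromosome."""
    rng = _stage_rngs(config.seed, 4)[1]
    per_chr = [config.n_snps // config.n_chromosomes] * config.n_chromosomes
    for k in range(config.n_snps % config.n_chromosomes):
        per_chr[k] += 1
    per_chr = [c for c in per_chr if c > 0]

    lo, hi = config.maf_range
    recs = pedigree.records
    inds = list(recs["individual"])

    chrom_names, positions, freqs_all = [], [], []
    haps = {ind: [] for ind in inds}  # list of (2, m_chr) blocks
    for c, m in enumerate(per_chr, start=1):
        freqs = rng.uniform(lo, hi, size=m)
        chrom_names += [str(c)] * m
        positions += list((np.arange(m) + 1) * config.snp_spacing_bp)
        freqs_all.append(freqs)
        founders = [i for i, s, d in zip(recs["individual"], recs["sire"], recs["dam"])
                    if s is None and d is None]
        fh = _founder_haplotypes(rng, 2 * len(founders), freqs, config.ld_decay_parameter)
        for k, ind in enumerate(founders):
            haps[ind].append(fh[2 * k: 2 * k + 2])
        r = 1.0 / max(m - 1, 1)
        for _, row in recs.iterrows():
            ind, sire, dam = row["individual"], row["sire"], row["dam"]
            if sire is None and dam is None:
                continue
            gam_s = _gametes(rng, haps[sire][c - 1], 1, r)[0]
            gam_d = _gametes(rng, haps[dam][c - 1], 1, r)[0]
            haps[ind].append(np.stack([gam_s, gam_d]))

    dosage = np.stack([np.concatenate([blk.sum(axis=0) for blk in haps[i]]) for i in inds])
    snp_ids = [f"snp{c}_{j}" for c, m in enumerate(per_chr, start=1) for j in range(m)]
    df = pd.DataFrame(dosage.astype(float), index=inds, columns=snp_ids)
    polarized, maf, _ = polarize_to_minor(df)
    snp_map = SnpMap(table=pd.DataFrame({
        "snp_id": snp_ids,
        "chromosome": chrom_names,
        "position_bp": positions,
        "allele_ref": "A",
        "allele_alt": "B",
        "maf": maf,
    }))
    return GenotypeMatrix(dosages=polarized, snp_map=snp_map)


def chain_precision(m: int, coupling: float = 0.25) -> np.ndarray:
    """Banded (chain) precision matrix Ω: unit diagonal, −coupling between
    adjacent metabolites; diagonally dominant hence positive definite for
    coupling < 0.5."""
    O = np.eye(m)
    idx = np.arange(m - 1)
    O[idx, idx + 1] = O[idx + 1, idx] = -coupling
    return O


def make_truth(
    config: SimConfig,
    genotypes: Optional[GenotypeMatrix] = None,
    planted: Sequence[tuple] = (),
    h2: Optional[Sequence[float]] = None,
    lambdas: Optional[Sequence[float]] = None,
    omega: Optional[np.ndarray] = None,
) -> SimulationTruth:
    """Assemble the ground truth: planted mQTL (given as (snp_id, trait_id,
    target PVE) triples), per-metabolite heritability and Box-Cox λ,
    residual precision Ω and covariate effect sizes."""
    rng = _stage_rngs(config.seed, 4)[2]
    m = config.n_metabolites
    mets = [f"met{k:03d}" for k in range(m)]

    h2_arr = rng.uniform(0.05, 0.6, size=m) if h2 is None else np.asarray(h2, dtype=float)
    lam_arr = (rng.choice([0.0, 0.25, 0.5, 1.0], size=m) if lambdas is None
               else np.asarray(lambdas, dtype=float))
    O = chain_precision(m) if omega is None else np.asarray(omega, dtype=float)

    # covariate effects sized so the fixed effects explain ~cov_var_share of
    # the latent variance (genetic + residual variance is normalized to 1)
    share = config.cov_var_share
    total = share / max(1.0 - share, 1e-12)
    v_each = total / 3.0
    betas = {}
    sd_w = 8.0  # carcass weight spread, kg
    for k, met in enumerate(mets):
        b_w = rng.choice([-1, 1]) * math.sqrt(v_each) / sd_w
        b_s = rng.choice([-1, 1]) * math.sqrt(v_each) / 0.5
        b_dates = rng.normal(0.0, math.sqrt(v_each), size=config.n_dates - 1)
        betas[met] = [b_w, b_s, *b_dates]
    cov_eff = pd.DataFrame.from_dict(
        betas, orient="index",
        columns=["beta_w", "beta_s"] + [f"beta_C{j + 1}" for j in range(config.n_dates - 1)],
    )

    planted_list = []
    for snp_id, trait_id, pve in planted:
        # a negative target PVE plants the same variance share with a
        # negative allele effect (useful for true ratio-QTL)
        if genotypes is None:
            raise ValueError("planted mQTL require a genotype matrix")
        maf_tab = genotypes.snp_map.table.set_index("snp_id")["maf"]
        maf = float(maf_tab[snp_id])
        if not (0 < maf <= 0.5):
            raise ValueError(f"planted SNP {snp_id} is monomorphic")
        share = abs(pve)
        beta = math.copysign(
            math.sqrt(share / (1.0 - share) / (2.0 * maf * (1.0 - maf))), pve
        )
        planted_list.append(PlantedQTL(snp_id, trait_id, beta, share))

    return SimulationTruth(
        planted_mqtl=planted_list,
        h2_by_metabolite=pd.Series(h2_arr, index=mets),
        lambda_by_metabolite=pd.Series(lam_arr, index=mets),
        precision_matrix=O,
        covariate_effects=cov_eff,
        seed=config.seed,
    )


def _inverse_boxcox(u: np.ndarray, lam: float) -> np.ndarray:
    if lam == 0.0:
        return np.exp(u)
    arg = lam * u + 1.0
    return np.power(np.maximum(arg, 1e-9), 1.0 / lam)


def simulate_metabolome(
    genotypes: GenotypeMatrix,
    pedigree: Optional[Pedigree],
    truth: SimulationTruth,
    config: SimConfig,
    K: Optional[np.ndarray] = None,
    latent_scale: float = 0.5,
    latent_location: float = 3.0,
) -> tuple[MetaboliteMatrix, SampleCovariates, SimulationTruth]:
    """Observed concentrations from the generative model.

    The latent genetic + residual part has unit variance (heritability is
    its genetic fraction) and is mapped onto the Box-Cox scale as
    μ0 + scale·(covariates + QTL + g + ε) before inverse transformation,
    zero-masking and outlier injection. ``K`` defaults to the centered GRM
    of ``genotypes`` normalized to unit mean diagonal.
    """
    rng = _stage_rngs(config.seed, 4)[3]
    mets = list(truth.h2_by_metabolite.index)
    m = len(mets)
    samples = genotypes.sample_ids
    n = len(samples)

    if K is None:
        from .kinship import centered_grm

        K = centered_grm(genotypes).matrix
    K = np.asarray(K, dtype=float)
    K = K / max(np.mean(np.diag(K)), 1e-12)
    L = np.linalg.cholesky(K + 1e-8 * np.eye(n))

    # covariates
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    weight = rng.normal(90.0, 8.0, size=n)
    dates = rng.integers(0, config.n_dates, size=n)
    cov_tab = pd.DataFrame(
        {"sex": sex, "carcass_weight": weight,
         "collection_date": [f"d{j}" for j in dates]},
        index=samples,
    )
    covariates = SampleCovariates(table=cov_tab)

    sex01 = (sex == "M").astype(float)
    date_dummies = np.zeros((n, config.n_dates - 1))
    for j in range(1, config.n_dates):
        date_dummies[:, j - 1] = (dates == j).astype(float)

    # residuals with network structure: rows ~ N(0, correlation of Ω^{-1})
    Sigma = np.linalg.inv(truth.precision_matrix)
    Dinv = 1.0 / np.sqrt(np.diag(Sigma))
    Sigma_corr = Sigma * np.outer(Dinv, Dinv)
    Lr = np.linalg.cholesky(Sigma_corr + 1e-10 * np.eye(m))
    E = rng.standard_normal((n, m)) @ Lr.T

    h2 = truth.h2_by_metabolite.to_numpy(dtype=float)
    G = L @ rng.standard_normal((n, m))  # columns ~ N(0, K)

    U = np.empty((n, m))
    planted_by_trait: dict = {}
    for q in truth.planted_mqtl:
        planted_by_trait.setdefault(q.trait_id, []).append(q)
    ce = truth.covariate_effects
    for k, met in enumerate(mets):
        t = (
            ce.loc[met, "beta_w"] * (weight - weight.mean())
            + ce.loc[met, "beta_s"] * sex01
            + date_dummies @ ce.loc[met].to_numpy(dtype=float)[2:]
            + math.sqrt(h2[k]) * G[:, k]
            + math.sqrt(1.0 - h2[k]) * E[:, k]
        )
        for q in planted_by_trait.get(met, []):
            x = genotypes.dosages[q.snp_id].to_numpy(dtype=float)
            x = np.nan_to_num(x, nan=np.nanmean(x))
            t = t + q.beta * (x - x.mean())
        U[:, k] = latent_location + latent_scale * t

    lam = truth.lambda_by_metabolite.to_numpy(dtype=float)
    Y = np.column_stack([_inverse_boxcox(U[:, k], lam[k]) for k in range(m)])

    # below-LOD censoring: the smallest zero_rate fraction of each metabolite
    if config.zero_rate > 0:
        n_zero = int(round(config.zero_rate * n))
        for k in range(m):
            if n_zero > 0:
                idx = np.argsort(Y[:, k])[:n_zero]
                Y[idx, k] = 0.0

    # multiplicative sample outliers hitting > 30% of metabolites
    if config.outlier_rate > 0:
        n_out = int(round(config.outlier_rate * n))
        out_samples = rng.choice(n, size=n_out, replace=False)
        n_hit = max(int(math.ceil(config.outlier_met_frac * m)), 1)
        for i in out_samples:
            hit = rng.choice(m, size=n_hit, replace=False)
            Y[i, hit] *= config.outlier_factor

    plates = pd.Series(
        [f"plate{(i % config.n_plates) + 1}" for i in range(n)], index=samples
    )
    matrix = MetaboliteMatrix(
        values=pd.DataFrame(Y, index=samples, columns=mets),
        plate_of_sample=plates,
    )
    return matrix, covariates, truth


def simulate_ggm_data(
    omega: np.ndarray, n: int, seed: Optional[int] = None
) -> pd.DataFrame:
    """Zero-mean Gaussian sample with covariance Ω⁻¹ (no genetics, no
    covariates): the minimal input for partial-correlation recovery."""
    O = np.asarray(omega, dtype=float)
    rng = np.random.default_rng(seed)
    Sigma = np.linalg.inv(O)
    L = np.linalg.cholesky(Sigma)
    X = rng.standard_normal((n, O.shape[0])) @ L.T
    return pd.DataFrame(X, columns=[f"met{k:03d}" for k in range(O.shape[0])])


def simulate_kp_cohort(
    n_per_group: int,
    kp_params_by_genotype: dict,
    trp_levels: Sequence[float],
    noise_cv: float = 0.1,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Nutrigenetic cohort: two genotype groups × two Trp timepoints.

    Per animal and timepoint each KP metabolite is the analytic steady state
    at the clamped Trp level, multiplied by unit-mean lognormal noise with
    coefficient of variation ``noise_cv``.
    """
    if len(trp_levels) != 2:
        raise ValueError("trp_levels must be (basal, supplemented)")
    if any(t <= 0 for t in trp_levels):
        raise ValueError("Trp levels must be positive")
    if len(kp_params_by_genotype) != 2:
        raise ValueError("expected exactly two genotype groups")
    rng = np.random.default_rng(seed)
    sigma2 = math.log(1.0 + noise_cv**2)
    mu_ln = -sigma2 / 2.0

    rows = []
    for geno, params in kp_params_by_genotype.items():
        if not isinstance(params, KPParameters):
            params = KPParameters(**params)
        for a in range(n_per_group):
            for t_idx, (timepoint, trp) in enumerate(zip(("basal", "supplemented"), trp_levels)):
                ss = analytic_steady_state(params, trp).state.as_array()
                if noise_cv > 0:
                    noise = np.exp(rng.normal(mu_ln, math.sqrt(sigma2), size=len(ss)))
                else:
                    noise = np.ones(len(ss))
                row = {"animal": f"{geno}_{a:02d}", "genotype": geno, "timepoint": timepoint}
                row.update(dict(zip(KP_SPECIES, ss * noise)))
                rows.append(row)
    return pd.DataFrame(rows)
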