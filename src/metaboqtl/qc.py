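"""Metabolite and sample quality control.

The cleaning pipeline applies, in order: (i) removal of metabolites entirely
missing or entirely zero in at least one plasma pool, (ii) removal of samples
deviating more than 1.5×IQR from the metabolite median for more than 30% of
metabolites, (iii) removal of samples with any remaining missing value, and
(iv) removal of metabolites whose inter-plate coefficient of variation on
pool samples exceeds the threshold. Zeros are then imputed from
Uniform(0, per-metabolite minimum nonzero concentration).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import MetaboliteMatrix

__all__ = [
    "QCReport",
    "filter_metabolites_pools",
    "flag_outlier_samples",
    "drop_incomplete_samples",
    "filter_metabolites_cv",
    "impute_zeros",
    "run_qc",
]


@dataclass
class QCReport:
    removed_metabolites: dict = field(default_factory=dict)  # id -> reason
    removed_samples: dict = field(default_factory=dict)  # id -> reason
    imputed_cells: int = 0
    interplate_cv: dict = field(default_factory=dict)  # metabolite -> CV

    def merge(self, other: "QCReport") -> "QCReport":
        return QCReport(
            removed_metabolites={**self.removed_metabolites, **other.removed_metabolites},
            removed_samples={**self.removed_samples, **other.removed_samples},
            imputed_cells=self.imputed_cells + other.imputed_cells,
            interplate_cv={**self.interplate_cv, **other.interplate_cv},
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id": k, "kind": "metabolite", "reason": v}
            for k, v in self.removed_metabolites.items()
        ] + [
            {"id": k, "kind": "sample", "reason": v}
            for k, v in self.removed_samples.items()
        ]
        return pd.DataFrame(rows, columns=["id", "kind", "reason"])


def _subset(matrix: MetaboliteMatrix, samples=None, metabolites=None) -> MetaboliteMatrix:
    vals = matrix.values
    if samples is not None:
        vals = vals.loc[samples]
    if metabolites is not None:
        vals = vals[metabolites]
    plate = matrix.plate_of_sample
    if plate is not None:
        plate = plate.reindex(vals.index)
    return MetaboliteMatrix(values=vals, plate_of_sample=plate)


def filter_metabolites_pools(
    matrix: MetaboliteMatrix, pool_samples: Sequence
) -> tuple[MetaboliteMatrix, QCReport]:
    """Drop metabolites with all-missing or all-zero values in ≥ 1 pool.

    A "pool" is the set of QC-pool rows of one plate; the rule is evaluated
    per plate so a metabolite failing on a single plate is removed.
    """
    pool_samples = list(pool_samples)
    if not pool_samples:
        raise ValueError("no pool samples given")
    pools = matrix.values.loc[pool_samples]
    if matrix.plate_of_sample is not None:
        groups = pools.groupby(matrix.plate_of_sample.loc[pool_samples])
    else:
        groups = [("all", pools)]

    removed: dict = {}
    for plate, block in groups:
        all_missing = block.isna().all(axis=0)
        all_zero = block.notna().all(axis=0) & (block.fillna(np.nan) == 0).all(axis=0)
        for met in block.columns[all_missing | all_zero]:
            removed.setdefault(met, f"pool-missing (plate {plate})")
    kept = [m for m in matrix.metabolite_ids if m not in removed]
    report = QCReport(removed_metabolites=removed)
    return _subset(matrix, metabolites=kept), report


def flag_outlier_samples(
    matrix: MetaboliteMatrix,
    iqr_mult: float = 1.5,
    outlier_frac: float = 0.30,
    exclude_samples: Sequence = (),
) -> tuple[MetaboliteMatrix, QCReport]:
    """Remove samples outside median ± 1.5·IQR for strictly > 30% of
    metabolites. With IQR 0 a value deviates only if it differs from the
    median. ``exclude_samples`` (e.g. pools) are kept but not tested."""
    vals = matrix.values
    med = vals.median(axis=0)
    q1, q3 = vals.quantile(0.25, axis=0), vals.quantile(0.75, axis=0)
    iqr = q3 - q1
    lo, hi = med - iqr_mult * iqr, med + iqr_mult * iqr
    deviant = (vals.lt(lo, axis=1) | vals.gt(hi, axis=1)) & vals.notna()
    frac = deviant.sum(axis=1) / vals.notna().sum(axis=1).clip(lower=1)
    is_outlier = frac > outlier_frac
    is_outlier[is_outlier.index.isin(exclude_samples)] = False
    removed = {s: f"outlier ({frac[s]:.1%} of metabolites deviant)" for s in vals.index[is_outlier]}
    kept = vals.index[~is_outlier]
    return _subset(matrix, samples=kept), QCReport(removed_samples=removed)


def drop_incomplete_samples(matrix: MetaboliteMatrix) -> tuple[MetaboliteMatrix, QCReport]:
    """Remove samples with at least one missing metabolite value."""
    if matrix.values.empty:
        warnings.warn("empty metabolite matrix", stacklevel=2)
        return matrix, QCReport()
    has_missing = matrix.values.isna().any(axis=1)
    removed = {s: "missing-value" for s in matrix.values.index[has_missing]}
    return _subset(matrix, samples=matrix.values.index[~has_missing]), QCReport(
        removed_samples=removed
    )


def filter_metabolites_cv(
    matrix: MetaboliteMatrix,
    pool_samples: Sequence,
    cv_threshold: float = 0.30,
    remove_high: bool = True,
) -> tuple[MetaboliteMatrix, QCReport]:
    """Inter-plate CV filter on pool samples.

    CV = sd/mean of per-plate pool means. Metabolites with CV ≥ threshold
    are removed (``remove_high=False`` inverts the rule for compatibility
    with a literal reading of the opposite convention; the applied rule is
    logged in the report).
    """
    pool_samples = list(pool_samples)
    if matrix.plate_of_sample is None:
        raise ValueError("inter-plate CV requires plate labels")
    pools = matrix.values.loc[pool_samples]
    plates = matrix.plate_of_sample.loc[pool_samples]
    if plates.nunique() < 2:
        raise ValueError("inter-plate CV requires pools on >= 2 plates")
    plate_means = pools.groupby(plates).mean()

    removed: dict = {}
    cvs: dict = {}
    for met in pools.columns:
        means = plate_means[met].dropna()
        mu = means.mean()
        if mu == 0 or len(means) < 2:
            removed[met] = "undefined CV"
            cvs[met] = np.nan
            continue
        cv = means.std(ddof=1) / mu
        cvs[met] = cv
        fails = cv >= cv_threshold if remove_high else cv < cv_threshold
        if fails:
            removed[met] = f"cv ({cv:.3f} {'>=' if remove_high else '<'} {cv_threshold})"
    kept = [m for m in matrix.metabolite_ids if m not in removed]
    report = QCReport(removed_metabolites=removed, interplate_cv=cvs)
    return _subset(matrix, metabolites=kept), report


def impute_zeros(matrix: MetaboliteMatrix, seed: Optional[int] = None) -> MetaboliteMatrix:
    """Replace zeros by draws from Uniform(0, min nonzero of the metabolite).

    Requires a complete matrix (run after :func:`drop_incomplete_samples`).
    """
    vals = matrix.values
    if vals.isna().any().any():
        raise ValueError("impute_zeros requires a complete matrix (no missing values)")
    rng = np.random.default_rng(seed)
    out = vals.copy()
    for met in vals.columns:
        col = vals[met].to_numpy(dtype=float)
        zeros = col == 0
        if not zeros.any():
            continue
        nonzero = col[~zeros]
        if nonzero.size == 0:
            raise ValueError(f"metabolite {met!r} entirely zero: minimum nonzero undefined")
        lo_draws = rng.uniform(0.0, nonzero.min(), size=int(zeros.sum()))
        col = col.copy()
        col[zeros] = lo_draws
        out[met] = col
    return MetaboliteMatrix(values=out, plate_of_sample=matrix.plate_of_sample)


def run_qc(
    matrix: MetaboliteMatrix,
    pool_samples: Sequence,
    cv_threshold: float = 0.30,
    iqr_mult: float = 1.5,
    outlier_frac: float = 0.30,
    seed: Optional[int] = None,
) -> tuple[MetaboliteMatrix, QCReport]:
    """Full QC pipeline (pool filter → outlier samples → incomplete samples
    → CV filter → zero imputation); pool rows are dropped from the output.

    Without pool samples the pool and inter-plate CV filters are skipped
    with a warning (they are defined on QC pools only).
    """
    pool_samples = list(pool_samples)
    if pool_samples:
        m1, r1 = filter_metabolites_pools(matrix, pool_samples)
    else:
        warnings.warn("no pool samples: pool and CV filters skipped", stacklevel=2)
        m1, r1 = matrix, QCReport()
    m2, r2 = flag_outlier_samples(m1, iqr_mult, outlier_frac, exclude_samples=pool_samples)
    m3, r3 = drop_incomplete_samples(m2)
    if pool_samples:
        m4, r4 = filter_metabolites_cv(
            m3, [s for s in pool_samples if s in m3.values.index], cv_threshold
        )
    else:
        m4, r4 = m3, QCReport()
    animals = [s for s in m4.values.index if s not in set(pool_samples)]
    m5 = _subset(m4, samples=animals)
    zeros_before = int((m5.values == 0).sum().sum())
    m6 = impute_zeros(m5, seed=seed)
    report = r1.merge(r2).merge(r3).merge(r4)
    report.imputed_cells = zeros_before
    return m6, report
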