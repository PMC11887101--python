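"""Shared typed containers for the metabolite-QTL pipeline.

All genomic coordinates are 1-based inclusive internally; BED input is
converted on read. Metabolite concentrations are in µM; missing values are
NaN. Genotype dosages count copies of the minor allele (0/1/2, NaN missing).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "MetaboliteMatrix",
    "SampleCovariates",
    "SnpMap",
    "GenotypeMatrix",
    "Pedigree",
    "GeneTable",
    "RelationshipMatrix",
    "polarize_to_minor",
]


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dup}")


@dataclass
class MetaboliteMatrix:
    """Samples × metabolites concentration table (µM).

    ``values`` is a DataFrame indexed by sample id with metabolite ids as
    columns. ``plate_of_sample`` maps each sample to a plate/batch label and
    may be None when no plate design exists.
    """

    values: pd.DataFrame
    plate_of_sample: Optional[pd.Series] = None
    metabolite_class: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "sample ids")
        _check_unique(self.values.columns, "metabolite ids")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValueError("negative concentrations are not allowed")
        if self.plate_of_sample is not None:
            self.plate_of_sample = self.plate_of_sample.reindex(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple:
        return self.values.shape


@dataclass
class SampleCovariates:
    """Per-sample fixed-effect covariates: sex, carcass weight, collection
    date (categorical, J ≥ 2 levels when used) and optional breed."""

    table: pd.DataFrame  # columns: sex, carcass_weight, collection_date[, breed]

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample ids")
        required = {"sex", "carcass_weight"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"covariate columns missing: {sorted(missing)}")

    def design_matrix(self, samples=None, include_breed: bool = False) -> pd.DataFrame:
        """Intercept + weight + sex + J−1 collection-date dummies
        (+ breed dummies when requested)."""
        tab = self.table if samples is None else self.table.loc[samples]
        if tab.isna().any().any():
            bad = tab.columns[tab.isna().any()].tolist()
            raise ValueError(f"incomplete covariate record in columns {bad}")
        cols = {"intercept": np.ones(len(tab))}
        cols["carcass_weight"] = tab["carcass_weight"].to_numpy(dtype=float)
        sex = pd.Categorical(tab["sex"])
        for lev in sex.categories[1:]:
            cols[f"sex_{lev}"] = (sex == lev).astype(float)
        if "collection_date" in tab.columns:
            date = pd.Categorical(tab["collection_date"])
            for lev in date.categories[1:]:
                cols[f"date_{lev}"] = (date == lev).astype(float)
        if include_breed and "breed" in tab.columns:
            breed = pd.Categorical(tab["breed"])
            for lev in breed.categories[1:]:
                cols[f"breed_{lev}"] = (breed == lev).astype(float)
        return pd.DataFrame(cols, index=tab.index)


@dataclass
class SnpMap:
    """Marker metadata: id, chromosome, 1-based position, alleles, MAF."""

    table: pd.DataFrame  # columns: snp_id, chromosome, position_bp, allele_ref, allele_alt, maf

    def __post_init__(self) -> None:
        _check_unique(self.table["snp_id"], "snp ids")
        if (self.table["position_bp"] <= 0).any():
            raise ValueError("positions must be positive (1-based)")
        maf = self.table["maf"].to_numpy(dtype=float)
        if np.any((maf < 0) | (maf > 0.5 + 1e-12)):
            raise ValueError("maf must lie in [0, 0.5] after polarization")

    def __len__(self) -> int:
        return len(self.table)

    def sorted_by_position(self) -> pd.DataFrame:
        return self.table.sort_values(["chromosome", "position_bp"], kind="mergesort")


def polarize_to_minor(dosages: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Flip columns so dosage counts the minor allele.

    Returns (polarized dosages, maf per SNP, flipped mask). Missing entries
    are ignored in the frequency computation.
    """
    X = dosages.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(X, axis=0) / 2.0
    flipped = freq > 0.5
    X = X.copy()
    X[:, flipped] = 2.0 - X[:, flipped]
    maf = np.where(flipped, 1.0 - freq, freq)
    return pd.DataFrame(X, index=dosages.index, columns=dosages.columns), maf, flipped


@dataclass
class GenotypeMatrix:
    """Samples × SNPs minor-allele dosage matrix with its marker map."""

    dosages: pd.DataFrame
    snp_map: SnpMap

    def __post_init__(self) -> None:
        if self.dosages.shape[1] != len(self.snp_map):
            raise ValueError("dosage column count does not match SNP map length")
        X = self.dosages.to_numpy(dtype=float)
        valid = np.isnan(X) | np.isin(X, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"dosage outside {{0,1,2,NA}} at sample "
                f"{self.dosages.index[bad[0]]!r}, snp {self.dosages.columns[bad[1]]!r}"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.dosages.index)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def imputed_dosages(self) -> np.ndarray:
        """Dosages with missing entries replaced by the per-SNP mean.

        Used only inside GRM/LD computations; stored data stay faithful.
        """
        X = self.dosages.to_numpy(dtype=float).copy()
        if np.isnan(X).any():
            with np.errstate(invalid="ignore"):
                mean = np.nanmean(X, axis=0)
            mean = np.where(np.isnan(mean), 0.0, mean)
            idx = np.where(np.isnan(X))
            X[idx] = mean[idx[1]]
        return X


@dataclass
class Pedigree:
    """Topologically ordered pedigree: individual, sire, dam, generation.

    Unknown parents are None. ``generation`` is the depth from founders.
    """

    records: pd.DataFrame  # columns: individual, sire, dam, generation

    def __post_init__(self) -> None:
        _check_unique(self.records["individual"], "pedigree individuals")
        known = set()
        for _, row in self.records.iterrows():
            for parent in (row["sire"], row["dam"]):
                if parent is not None and parent not in known:
                    raise ValueError(
                        f"pedigree not topologically ordered: parent {parent!r} "
                        f"appears after (or never before) {row['individual']!r}"
                    )
            known.add(row["individual"])

    @property
    def individuals(self) -> list:
        return list(self.records["individual"])

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GeneTable:
    """Gene annotation with 1-based inclusive coordinates."""

    table: pd.DataFrame  # columns: gene_id, chromosome, start_bp, end_bp, strand, name

    def __post_init__(self) -> None:
        if (self.table["start_bp"] > self.table["end_bp"]).any():
            raise ValueError("gene start must be <= end")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class RelationshipMatrix:
    """Additive relationship (pedigree A) or centered genomic K."""

    kind: str  # "pedigree_A" | "genomic_K"
    matrix: np.ndarray
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("relationship matrix must be square")
        if not np.allclose(M, M.T, atol=1e-8):
            raise ValueError("relationship matrix must be symmetric")
        self.matrix = M

    @property
    def n(self) -> int:
        return self.matrix.shape[0]
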