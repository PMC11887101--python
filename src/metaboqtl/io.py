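"""Readers and writers for the text formats the pipeline touches.

Supported inputs: metabolite/covariate/pedigree CSV, PLINK .raw-style or CSV
dosage text, GFF3 and BED gene annotation. All tabular outputs are TSV with
a commented header carrying the package version and the seed in use.
"""
from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import (
    GeneTable,
    GenotypeMatrix,
    MetaboliteMatrix,
    Pedigree,
    SampleCovariates,
    SnpMap,
    polarize_to_minor,
)

__all__ = [
    "read_metabolite_csv",
    "write_metabolite_csv",
    "read_covariates_csv",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_pedigree",
    "write_pedigree",
    "read_gene_annotation",
    "write_tsv",
]


def write_tsv(df: pd.DataFrame, path, seed: Optional[int] = None, index: bool = False) -> None:
    """TSV with a commented provenance header."""
    with open(path, "w") as fh:
        fh.write(f"# metaboqtl {__version__}")
        if seed is not None:
            fh.write(f" seed={seed}")
        fh.write("\n")
        df.to_csv(fh, sep="\t", index=index)


def read_metabolite_csv(path, plate_column: Optional[str] = None) -> MetaboliteMatrix:
    """Read a samples × metabolites CSV (header of metabolite ids, one row
    per sample; first column is the sample id). Empty cells become missing."""
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                header = [h.strip() for h in line.rstrip("\n").split(",")][1:]
                break
        else:
            header = []
    seen = set()
    for h in header:
        if h in seen:
            raise ValueError(f"duplicate metabolite id in header: {h!r}")
        seen.add(h)
    df = pd.read_csv(path, index_col=0, comment="#")
    plate = None
    if plate_column is not None:
        if plate_column not in df.columns:
            raise ValueError(f"plate column {plate_column!r} not found")
        plate = df[plate_column].astype(str)
        df = df.drop(columns=[plate_column])
    raw = pd.read_csv(path, index_col=0, comment="#", dtype=str)
    if plate_column is not None:
        raw = raw.drop(columns=[plate_column])
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(f"non-numeric value at row {row!r}, column {col!r}")
        df[col] = coerced
    return MetaboliteMatrix(values=df.astype(float), plate_of_sample=plate)


def write_metabolite_csv(matrix: MetaboliteMatrix, path) -> None:
    df = matrix.values.copy()
    if matrix.plate_of_sample is not None:
        df.insert(0, "plate", matrix.plate_of_sample)
    df.to_csv(path)


def read_covariates_csv(path) -> SampleCovariates:
    df = pd.read_csv(path, index_col=0, comment="#")
    return SampleCovariates(table=df)


def _snp_map_from_raw_header(names: list[str]) -> pd.DataFrame:
    """PLINK .raw headers look like ``rs123_A``: id plus counted allele."""
    snp_ids, alts = [], []
    for name in names:
        if "_" in name:
            sid, allele = name.rsplit("_", 1)
        else:
            sid, allele = name, "A"
        snp_ids.append(sid)
        alts.append(allele)
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chromosome": "0",
            "position_bp": np.arange(1, len(names) + 1),
            "allele_ref": "N",
            "allele_alt": alts,
        }
    )


def read_genotype_matrix(path, format: str = "csv_dosage", snp_map: Optional[pd.DataFrame] = None) -> GenotypeMatrix:
    """Read 0/1/2 dosages; polarize so dosage counts the minor allele.

    ``csv_dosage``: first column sample id, remaining columns SNP ids.
    ``plink_raw``: whitespace-separated .raw with FID IID PAT MAT SEX
    PHENOTYPE then SNP_ALLELE columns.

    An optional ``snp_map`` DataFrame (snp_id, chromosome, position_bp,
    allele_ref, allele_alt) overrides positional metadata.
    """
    if format == "csv_dosage":
        df = pd.read_csv(path, index_col=0, comment="#")
    elif format == "plink_raw":
        raw = pd.read_csv(path, sep=r"\s+")
        meta_cols = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in raw.columns]
        df = raw.drop(columns=meta_cols)
        df.index = raw["IID"] if "IID" in raw.columns else raw.index
        df.columns = [c for c in df.columns]
    else:
        raise ValueError(f"unknown genotype format {format!r}")

    X = df.apply(pd.to_numeric, errors="coerce").astype(float)
    arr = X.to_numpy()
    valid = np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0))
    if not valid.all():
        i, j = np.argwhere(~valid)[0]
        raise ValueError(
            f"dosage outside {{0,1,2,NA}} at sample {X.index[i]!r}, snp {X.columns[j]!r}"
        )

    if format == "plink_raw":
        map_df = _snp_map_from_raw_header(list(X.columns))
        X.columns = map_df["snp_id"]
    elif snp_map is not None:
        map_df = snp_map.copy().reset_index(drop=True)
    else:
        map_df = pd.DataFrame(
            {
                "snp_id": list(X.columns),
                "chromosome": "0",
                "position_bp": np.arange(1, X.shape[1] + 1),
                "allele_ref": "N",
                "allele_alt": "N",
            }
        )

    polarized, maf, flipped = polarize_to_minor(X)
    map_df = map_df.copy()
    if flipped.any():
        ref = map_df["allele_ref"].to_numpy().copy()
        alt = map_df["allele_alt"].to_numpy().copy()
        ref[flipped], alt[flipped] = alt[flipped].copy(), ref[flipped].copy()
        map_df["allele_ref"], map_df["allele_alt"] = ref, alt
    map_df["maf"] = maf
    return GenotypeMatrix(dosages=polarized, snp_map=SnpMap(table=map_df))


def write_genotype_matrix(genotypes: GenotypeMatrix, path) -> None:
    """CSV dosage export; pair with the SNP map written separately."""
    df = genotypes.dosages.copy()
    # keep 0/1/2 integers readable, NaN as empty
    df.to_csv(path, float_format="%.0f")


def read_pedigree(path) -> Pedigree:
    """CSV with columns individual,sire,dam; '0' or empty means unknown.

    Records are topologically sorted and generation depth is computed; a
    cycle or a duplicated individual is an error.
    """
    df = pd.read_csv(path, dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("individual", "sire", "dam"):
        if col not in df.columns:
            raise ValueError(f"pedigree file lacks column {col!r}")
    if df["individual"].duplicated().any():
        dup = df["individual"][df["individual"].duplicated()].tolist()
        raise ValueError(f"individual listed twice: {dup}")

    def norm(v):
        if pd.isna(v) or str(v).strip() in ("", "0"):
            return None
        return str(v).strip()

    parents = {
        str(r["individual"]).strip(): (norm(r["sire"]), norm(r["dam"]))
        for _, r in df.iterrows()
    }
    return build_pedigree(parents)


def build_pedigree(parents: dict) -> Pedigree:
    """Topologically sort {individual: (sire, dam)} and compute generations."""
    depth: dict = {}

    def generation(ind, stack=()):
        if ind in stack:
            raise ValueError(f"pedigree cycle involving {ind!r}")
        if ind in depth:
            return depth[ind]
        sire, dam = parents.get(ind, (None, None))
        g = 0
        for p in (sire, dam):
            if p is not None and p in parents:
                g = max(g, generation(p, stack + (ind,)) + 1)
            elif p is not None:
                g = max(g, 1)  # parent outside the file counts as a founder
        depth[ind] = g
        return g

    for ind in parents:
        generation(ind)
    order = sorted(parents, key=lambda i: (depth[i], str(i)))
    recs = pd.DataFrame(
        {
            "individual": order,
            "sire": [parents[i][0] if parents[i][0] in parents else None for i in order],
            "dam": [parents[i][1] if parents[i][1] in parents else None for i in order],
            "generation": [depth[i] for i in order],
        }
    )
    return Pedigree(records=recs)


def write_pedigree(pedigree: Pedigree, path) -> None:
    df = pedigree.records[["individual", "sire", "dam"]].copy()
    df = df.fillna("0")
    df.to_csv(path, index=False)


def read_gene_annotation(path, format: str = "gff3") -> GeneTable:
    """Gene features only. BED (0-based half-open) is converted to 1-based
    inclusive; GFF3 coordinates are used as printed."""
    rows = []
    if format == "gff3":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 9:
                    raise ValueError(f"malformed GFF3 line {lineno}: expected 9 fields")
                chrom, _src, ftype, start, end, _score, strand, _frame, attrs = fields
                if ftype != "gene":
                    continue
                try:
                    start_bp, end_bp = int(start), int(end)
                except ValueError:
                    raise ValueError(f"malformed GFF3 line {lineno}: non-integer coordinates")
                attr = dict(
                    kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                )
                gid = attr.get("ID", f"gene{len(rows) + 1}")
                rows.append(
                    {
                        "gene_id": gid,
                        "chromosome": chrom,
                        "start_bp": start_bp,
                        "end_bp": end_bp,
                        "strand": strand,
                        "name": attr.get("Name", gid),
                    }
                )
    elif format == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                if len(fields) < 3:
                    raise ValueError(f"malformed BED line {lineno}: fewer than 3 fields")
                chrom = fields[0]
                try:
                    start0, end0 = int(fields[1]), int(fields[2])
                except ValueError:
                    raise ValueError(f"malformed BED line {lineno}: non-integer coordinates")
                name = fields[3] if len(fields) > 3 else f"gene{len(rows) + 1}"
                strand = fields[5] if len(fields) > 5 else "."
                rows.append(
                    {
                        "gene_id": name,
                        "chromosome": chrom,
                        "start_bp": start0 + 1,  # 0-based half-open -> 1-based inclusive
                        "end_bp": end0,
                        "strand": strand,
                        "name": name,
                    }
                )
    else:
        raise ValueError(f"unknown annotation format {format!r}")

    if not rows:
        warnings.warn("no gene features found in annotation", stacklevel=2)
        return GeneTable(
            table=pd.DataFrame(
                columns=["gene_id", "chromosome", "start_bp", "end_bp", "strand", "name"]
            ).astype({"start_bp": int, "end_bp": int})
        )
    return GeneTable(table=pd.DataFrame(rows))
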