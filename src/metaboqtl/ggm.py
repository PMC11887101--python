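"""Gaussian graphical models over normalized metabolite residuals.

Edges connect metabolite pairs whose full-order partial correlation
coefficient (PCC) — the pairwise correlation conditioned on every other
metabolite, obtained by inverting the correlation matrix:
PCC_ij = −Ω_ij/√(Ω_ii·Ω_jj) — exceeds a threshold (default 0.3, strict,
signed). A genotype-corrected variant first replaces each metabolite by its
residuals from a regression on mQTL lead-SNP genotype indicator (dummy)
variables, removing edges that are driven by a shared genetic effect.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CorrelationNetwork",
    "pearson_matrix",
    "partial_correlation_matrix",
    "build_ggm",
    "genotype_corrected_pcc",
    "export_network",
]


@dataclass
class CorrelationNetwork:
    nodes: list
    pearson: pd.DataFrame
    pcc: pd.DataFrame
    edges: pd.DataFrame  # columns: a, b, pcc
    singletons: list
    threshold: float
    corrected: bool = False
    corrected_snps: list = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def pearson_matrix(normalized: pd.DataFrame) -> pd.DataFrame:
    """Product-moment correlation matrix; zero-variance columns are an
    error (no correlation is defined for a constant trait)."""
    X = pd.DataFrame(normalized)
    if X.isna().any().any():
        raise ValueError("missing values not allowed")
    sd = X.std(ddof=0)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"zero-variance columns: {bad}")
    r = np.corrcoef(X.to_numpy(dtype=float), rowvar=False)
    return pd.DataFrame(r, index=X.columns, columns=X.columns)


def partial_correlation_matrix(
    normalized: pd.DataFrame,
    ridge_if_singular: bool = True,
    condition_limit: float = 1e10,
    ridge: float = 1e-4,
) -> pd.DataFrame:
    """Full-order partial correlations by matrix inversion.

    When the correlation matrix is ill-conditioned (condition number above
    ``condition_limit``), a small ridge is added to its diagonal and a
    warning issued; with ``ridge_if_singular=False`` this is an error.
    """
    r = pearson_matrix(normalized)
    R = r.to_numpy()
    cond = np.linalg.cond(R)
    if cond > condition_limit:
        if not ridge_if_singular:
            raise ValueError(f"correlation matrix singular (cond={cond:.2e})")
        warnings.warn(
            f"correlation matrix ill-conditioned (cond={cond:.2e}); ridge applied",
            stacklevel=2,
        )
        R = R + ridge * np.eye(len(R))
    Om = np.linalg.inv(R)
    denom = np.sqrt(np.outer(np.diag(Om), np.diag(Om)))
    P = -Om / denom
    np.fill_diagonal(P, 1.0)
    return pd.DataFrame(P, index=r.index, columns=r.columns)


def build_ggm(
    pcc: pd.DataFrame,
    threshold: float = 0.3,
    absolute: bool = False,
    pearson: Optional[pd.DataFrame] = None,
) -> CorrelationNetwork:
    """Edges where PCC > threshold (strict; signed by default, absolute
    value with ``absolute=True``); remaining nodes are singletons."""
    P = pcc.to_numpy()
    nodes = list(pcc.columns)
    rows = []
    m = len(nodes)
    for i in range(m):
        for j in range(i + 1, m):
            v = abs(P[i, j]) if absolute else P[i, j]
            if v > threshold:
                rows.append({"a": nodes[i], "b": nodes[j], "pcc": P[i, j]})
    edges = pd.DataFrame(rows, columns=["a", "b", "pcc"])
    connected = set(edges["a"]) | set(edges["b"])
    singletons = [nd for nd in nodes if nd not in connected]
    return CorrelationNetwork(
        nodes=nodes,
        pearson=pcc if pearson is None else pearson,
        pcc=pcc,
        edges=edges,
        singletons=singletons,
        threshold=threshold,
    )


def _snp_dummies(x: np.ndarray, snp_id: str) -> Optional[np.ndarray]:
    """Two indicator columns (het, hom-alt) for one SNP's 0/1/2 dosages;
    None when the SNP is monomorphic. Missing dosages go to the major
    homozygote class."""
    x = np.nan_to_num(np.asarray(x, dtype=float), nan=0.0)
    levels = np.unique(x)
    if len(levels) < 2:
        return None
    cols = [(x == lev).astype(float) for lev in levels[1:]]
    return np.column_stack(cols)


def genotype_corrected_pcc(
    normalized: pd.DataFrame,
    genotypes,
    mqtl_leads: Sequence[str],
    threshold: float = 0.3,
    absolute: bool = False,
) -> CorrelationNetwork:
    """GGM after regressing out mQTL lead-SNP genotype factors.

    Each metabolite is replaced by its least-squares residuals on an
    intercept plus the dummy-coded genotypes of the lead SNPs; Pearson and
    partial correlations are then computed as usual. Monomorphic leads are
    dropped with a warning; with no usable SNPs the result equals the
    uncorrected network.
    """
    X_cols = [np.ones(len(normalized))]
    used = []
    for snp_id in mqtl_leads:
        x = genotypes.dosages[snp_id].to_numpy(dtype=float)
        dummies = _snp_dummies(x, snp_id)
        if dummies is None:
            warnings.warn(f"lead SNP {snp_id} monomorphic: dropped", stacklevel=2)
            continue
        X_cols.append(dummies)
        used.append(snp_id)
    X = np.column_stack(X_cols)
    Y = pd.DataFrame(normalized).to_numpy(dtype=float)
    Q, _ = np.linalg.qr(X)
    resid = Y - Q @ (Q.T @ Y)
    resid_df = pd.DataFrame(resid, index=pd.DataFrame(normalized).index,
                            columns=pd.DataFrame(normalized).columns)
    pcc = partial_correlation_matrix(resid_df)
    net = build_ggm(pcc, threshold=threshold, absolute=absolute,
                    pearson=pearson_matrix(resid_df))
    net.corrected = True
    net.corrected_snps = used
    return net


def export_network(network: CorrelationNetwork, path, format: str = "edge_tsv") -> None:
    """Write the network: ``edge_tsv`` (a, b, pcc), ``graphml`` (singletons
    preserved as isolated nodes), or ``sif`` (singletons omitted, with a
    warning)."""
    if format == "edge_tsv":
        network.edges.to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        G = nx.Graph()
        G.add_nodes_from(network.nodes)
        for _, e in network.edges.iterrows():
            G.add_edge(e["a"], e["b"], pcc=float(e["pcc"]))
        nx.write_graphml(G, path)
    elif format == "sif":
        if network.singletons:
            warnings.warn("sif format omits singleton nodes", stacklevel=2)
        with open(path, "w") as fh:
            for _, e in network.edges.iterrows():
                fh.write(f"{e['a']}\tpcc\t{e['b']}\n")
    else:
        raise ValueError(f"unknown format {format!r}")
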