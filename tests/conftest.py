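import numpy as np
import pandas as pd
import pytest

from metaboqtl.datamodel import GenotypeMatrix, SnpMap
from metaboqtl.kinship import centered_grm
from metaboqtl.simulate import SimConfig, simulate_genotypes, simulate_pedigree


@pytest.fixture(scope="session")
def small_cohort():
    """~220-animal two-generation cohort with 300 LD-structured SNPs."""
    cfg = SimConfig(
        n_founders=60, n_generations=2, litter_size=3,
        n_snps=300, n_chromosomes=3, n_metabolites=6,
        zero_rate=0.0, outlier_rate=0.0, seed=1234,
    )
    ped = simulate_pedigree(cfg)
    geno = simulate_genotypes(ped, cfg)
    K = centered_grm(geno)
    return cfg, ped, geno, K


def genotype_matrix_from_array(X, positions=None, chrom="1"):
    """Wrap a raw dosage array in a GenotypeMatrix (tests convenience)."""
    X = np.asarray(X, dtype=float)
    m = X.shape[1]
    ids = [f"s{j}" for j in range(m)]
    freq = X.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    tab = pd.DataFrame({
        "snp_id": ids,
        "chromosome": chrom,
        "position_bp": np.arange(1, m + 1) * 1000 if positions is None else positions,
        "allele_ref": "A",
        "allele_alt": "B",
        "maf": maf,
    })
    return GenotypeMatrix(dosages=pd.DataFrame(X, columns=ids), snp_map=SnpMap(table=tab))
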