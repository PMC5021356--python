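import numpy as np
import pandas as pd
import pytest

from genepair import CausalEffect, SimConfig, simulate_cohort
from genepair.matrix import GenotypeMatrix


def make_matrix(dos, snp_ids=None, pos=None, chrom="1", info=None, samples=None):
    """Small GenotypeMatrix from a raw dosage array."""
    dos = np.asarray(dos, dtype=float)
    n, m = dos.shape
    snp_ids = snp_ids or [f"s{j + 1}" for j in range(m)]
    variants = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
            "ref": "A",
            "alt": "B",
            "info_score": info if info is not None else np.nan,
        }
    )
    G = GenotypeMatrix(dos, samples or [f"I{i + 1}" for i in range(n)], variants)
    G.refresh_metadata()
    return G


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture(scope="session")
def null_cohort():
    """No genetic effects, covariates only; reused by calibration tests."""
    return simulate_cohort(SimConfig(n_samples=1200, n_snps=40, gene_count=8, seed=101))


@pytest.fixture(scope="session")
def interaction_cohort():
    """One planted gene-pair interaction, moderate effect."""
    cfg = SimConfig(
        n_samples=3000,
        n_snps=40,
        gene_count=8,
        snps_per_gene=5,
        seed=202,
        causal_spec=(CausalEffect("interaction", ("G002", "G006"), np.log(2.5)),),
    )
    return simulate_cohort(cfg)
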