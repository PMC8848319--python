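import numpy as np
import pytest

from netepi import (
    GenotypeDataset,
    SnpRecord,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def tiny_dataset() -> GenotypeDataset:
    """3 samples x 2 SNPs, one missing call, handy for format round-trips."""
    return GenotypeDataset(
        sample_ids=["s1", "s2", "s3"],
        snps=[SnpRecord("rsA", "1", 100, "A", "G"), SnpRecord("rsB", "2", 200, "C", "T")],
        genotypes=np.array([[0, 2], [1, -1], [2, 1]], dtype=np.int8),
        phenotype=np.array([0, 1, 1], dtype=np.int8),
    )


@pytest.fixture(scope="session")
def null_study():
    """Session-wide null simulation (no genetic effects) used by several tests."""
    cfg = SimulationConfig(seed=42)
    return cfg, simulate_dataset(cfg)


@pytest.fixture(scope="session")
def planted_study():
    """One planted gene-pair interaction strong enough to detect at n=2000."""
    cfg = SimulationConfig(
        seed=7,
        n_samples=2000,
        n_snps=40,
        n_genes=8,
        n_gene_edges=12,
        within_block_corr=0.0,
        maf_range=(0.3, 0.3),
        planted_models=[("G1", "G5", 0.6)],
    )
    return cfg, simulate_dataset(cfg)
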