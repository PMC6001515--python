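"""Shared fixtures.

The two 1,000-replicate experiments (null calibration and power) are
expensive, so they are session-scoped and shared between the property
tests and the acceptance tests.
"""

import numpy as np
import pytest

from polaris import GenotypeDataset, ScenarioAConfig, SnpRecord, run_experiment

MASTER_SEED = 731


@pytest.fixture(scope="session")
def null_experiment():
    """Scenario A with no associated SNP: 100 SNPs (10-SNP block at r2 = 0.8),
    N = 10,000 test / 10,000 discovery, 30% cases, 1,000 replicates."""
    cfg = ScenarioAConfig(causal_or=1.0)
    return run_experiment(cfg, methods=("POLARIS",), n_replicates=1000,
                          seed=MASTER_SEED)


@pytest.fixture(scope="session")
def power_experiment():
    """Scenario A with the causal block SNP at OR 1.1; POLARIS and the PCA
    comparator on the test half share each replicate's data (paired)."""
    cfg = ScenarioAConfig(causal_or=1.1)
    return run_experiment(cfg, methods=("POLARIS", "PCA_FTEST_test_only"),
                          n_replicates=1000, seed=MASTER_SEED)


def make_dataset(genotypes, phenotype=None, chrom="1", pos_step=1000,
                 alleles=("A", "G")) -> GenotypeDataset:
    """Small in-memory dataset with auto-generated SNP records."""
    genotypes = np.asarray(genotypes, dtype=float)
    n, m = genotypes.shape
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(genotypes, axis=0) / 2
    mafs = np.minimum(freq, 1 - freq)
    snps = [SnpRecord(id=f"rs{i + 1}", chrom=chrom, pos=(i + 1) * pos_step,
                      allele1=alleles[0], allele2=alleles[1], maf=float(mafs[i]))
            for i in range(m)]
    if phenotype is None:
        phenotype = np.zeros(n)
        phenotype[: n // 2] = 1
    return GenotypeDataset(genotypes=genotypes, snps=snps,
                           phenotype=np.asarray(phenotype, dtype=float))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
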