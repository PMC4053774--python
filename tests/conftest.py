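import numpy as np
import pandas as pd
import pytest

from breedscan import simulate as sim
from breedscan.datatypes import GenotypeDataset, make_samples, make_snps


def build_dataset(genotypes, phenotype=None, age=None, breed=None, bp=None, chrom=None):
    """Small handmade dataset: rows are samples, columns SNPs."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    sample_ids = [f"s{i}" for i in range(n)]
    snp_ids = [f"m{j}" for j in range(m)]
    if bp is None:
        bp = [1000 * (j + 1) for j in range(m)]
    if chrom is None:
        chrom = ["chr1"] * m
    samples = make_samples(sample_ids, phenotype=phenotype, age_years=age, breed=breed)
    snps = make_snps(snp_ids, chrom, bp)
    return GenotypeDataset(samples, snps, g)


@pytest.fixture(scope="session")
def breed_pair():
    """Two breeds, strong vs weak bottleneck, shared SNP map."""
    cfg = sim.SimulationConfig(
        n_breeds_gwas=2, n_reference_breeds=0, samples_per_breed=40,
        founders_per_breed={"gwas1": 20, "gwas2": 200},
        n_chromosomes=1, n_snps=600, generations=25, seed=42,
    )
    datasets, truth = sim.simulate_breed_panel(cfg)
    return datasets, truth


@pytest.fixture(scope="session")
def cohort():
    """One GWAS-style breed with a strong planted risk locus and phenotypes."""
    cfg = sim.SimulationConfig(
        n_breeds_gwas=1, n_reference_breeds=0, samples_per_breed=150,
        founders_per_breed=200, n_chromosomes=2, n_snps=1000,
        generations=10, seed=7,
        risk_loci=[sim.RiskLocus("chr1", 25_000_000, 8.0, 0.15)],
    )
    datasets, truth = sim.simulate_breed_panel(cfg)
    ds = sim.assign_phenotypes(datasets["gwas1"], truth, 0.5, seed=8)
    return ds, truth
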