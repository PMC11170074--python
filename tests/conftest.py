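import numpy as np
import pytest

from crmcval.genomic_io import GenomeManifest, GenomicInterval
from crmcval.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The full study-scale synthetic dataset (500 CRMCs, f=0.5, x=0.10)."""
    return generate_dataset(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def small_dataset():
    """A fast small dataset for unit-level checks."""
    cfg = SyntheticConfig(
        seed=7, n_chroms=2, chrom_length_bp=60_000, n_covered_per_chrom=2,
        n_crmcs=20, crmc_length_mean=600.0, crmc_length_sd=150.0,
        min_crmc_length=100, min_gap=200, n_tissues=6, n_lineage_blocks=2,
    )
    return generate_dataset(cfg)


def random_small_config(rng: np.random.Generator) -> SyntheticConfig:
    """A randomized <=100 kb genome configuration for oracle cross-checks."""
    return SyntheticConfig(
        seed=int(rng.integers(0, 2**31 - 1)),
        n_chroms=2,
        chrom_length_bp=int(rng.integers(20_000, 50_000)),
        n_covered_per_chrom=2,
        coverage_fraction=float(rng.uniform(0.4, 0.7)),
        n_crmcs=int(rng.integers(6, 14)),
        crmc_length_mean=float(rng.uniform(400, 800)),
        crmc_length_sd=120.0,
        min_crmc_length=100,
        min_gap=150,
        element_fraction=float(rng.uniform(0.4, 0.9)),
        truncation_fraction=float(rng.uniform(0.3, 0.9)),
        extension_fraction=float(rng.choice([0.0, 0.1, 0.2])),
    )


@pytest.fixture
def tiny_manifest():
    return GenomeManifest([("chr1", 10_000), ("chr2", 8_000)])


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)
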