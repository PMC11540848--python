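import numpy as np
import pandas as pd
import pytest

from xqtl.synthdata import SimConfig, TraitMatrix, simulate_genotypes, simulate_traits


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(n_samples=200, n_variants=100, n_blocks=5, ld_rho=0.6, seed=11)


@pytest.fixture(scope="session")
def small_geno(small_cfg):
    return simulate_genotypes(small_cfg)


@pytest.fixture(scope="session")
def small_traits(small_cfg, small_geno):
    return simulate_traits(small_geno, small_cfg)


def make_trait_matrix(values: np.ndarray, chrom: str = "chr1", tss: int = 150_001) -> TraitMatrix:
    """Single-chromosome trait matrix helper for window-level tests."""
    values = np.atleast_2d(values)
    n_traits, n_samples = values.shape
    meta = pd.DataFrame(
        [
            dict(
                trait_id=f"t{i}",
                gene_id=f"g{i}",
                chrom=chrom,
                tss=tss,
                gene_start=tss,
                gene_end=tss + 50_000,
                strand="+",
            )
            for i in range(n_traits)
        ]
    )
    return TraitMatrix(values, meta, [f"S{j + 1:04d}" for j in range(n_samples)])
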