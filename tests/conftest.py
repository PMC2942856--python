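import numpy as np
import pytest

from bmagene.io import GenotypeTable


def random_table(rng: np.random.Generator, n: int, l: int, maf=None) -> GenotypeTable:
    """Random genotype table under HWE with a random phenotype."""
    maf = rng.uniform(0.1, 0.5, size=l) if maf is None else np.full(l, maf)
    g = rng.binomial(2, maf, size=(n, l)).astype(np.int8)
    y = rng.integers(0, 2, size=n).astype(np.int8)
    return GenotypeTable(genotypes=g, phenotype=y)


def table_from_counts(cell_counts) -> GenotypeTable:
    """Single-locus table realizing exact (genotype -> cases, controls)
    counts, e.g. {0: (10, 20), 1: (20, 10), 2: (5, 5)}."""
    geno, pheno = [], []
    for g, (cases, controls) in cell_counts.items():
        geno += [g] * (cases + controls)
        pheno += [1] * cases + [0] * controls
    return GenotypeTable(
        genotypes=np.array(geno, dtype=np.int8)[:, None],
        phenotype=np.array(pheno, dtype=np.int8),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20231101)


@pytest.fixture
def small_table(rng):
    return random_table(rng, 60, 4)
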