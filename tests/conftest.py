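import numpy as np
import pytest

from whalepop.genotype_io import MISSING, GenotypeMatrix


def make_matrix(genotypes, positions=None, chrom="chr1", depths=None, cohorts=None):
    """Small GenotypeMatrix helper: genotypes is (sites x individuals)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_ind = g.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1)
    return GenotypeMatrix(
        chrom_ids=np.array([chrom] * n_sites, dtype=object),
        positions=np.asarray(positions),
        ref_allele=np.array(["A"] * n_sites, dtype=object),
        alt_alleles=[["T"]] * n_sites,
        genotypes=g,
        sample_ids=[f"s{i}" for i in range(n_ind)],
        depths=depths,
        cohort_labels=cohorts,
    )


@pytest.fixture
def random_matrix():
    """300 biallelic sites x 12 individuals with some missing calls."""
    rng = np.random.default_rng(42)
    p = rng.uniform(0.05, 0.95, size=300)
    g = (rng.random((300, 12, 2)) < p[:, None, None]).sum(axis=2).astype(np.int8)
    miss = rng.random((300, 12)) < 0.03
    g[miss] = MISSING
    return make_matrix(g)
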