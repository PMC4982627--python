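import numpy as np
import pytest

from rooscan.hapstats import HaplotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_matrix(rng, n, m, region_length=10_000):
    """Random polymorphic haplotype matrix (every column segregating)."""
    alleles = rng.integers(0, 2, size=(n, m), dtype=np.int8)
    counts = alleles.sum(axis=0)
    for j in np.flatnonzero((counts == 0) | (counts == n)):
        alleles[rng.integers(n), j] ^= 1  # force the column polymorphic
    positions = np.sort(rng.choice(np.arange(1, region_length), size=m, replace=False))
    return HaplotypeMatrix(alleles, positions)


@pytest.fixture
def small_matrix():
    """Fixed n=6, 10-site matrix used for hand-checkable statistics."""
    alleles = np.array([
        [0, 1, 0, 0, 1, 0, 1, 0, 0, 1],
        [0, 1, 0, 1, 1, 0, 0, 0, 1, 1],
        [1, 0, 0, 1, 0, 1, 0, 0, 1, 0],
        [1, 0, 1, 1, 0, 1, 0, 1, 0, 0],
        [0, 1, 0, 0, 1, 0, 1, 0, 0, 1],
        [1, 0, 1, 1, 0, 1, 0, 1, 0, 0],
    ], dtype=np.int8)
    positions = np.array([100, 250, 400, 480, 700, 910, 1200, 1450, 1700, 1950])
    return HaplotypeMatrix(alleles, positions)
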