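import numpy as np
import pytest

from popkit.io import GenotypeMatrix, MarkerRecord


def make_matrix(calls, chromosomes=None, positions=None, samples=None,
                alleles=None):
    """Build a GenotypeMatrix from a (n, N) array with sane defaults."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if chromosomes is None:
        chromosomes = ["1"] * m
    if positions is None:
        positions = [1000 * (k + 1) for k in range(m)]
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    if alleles is None:
        alleles = [("A", "G")] * m
    markers = [
        MarkerRecord(f"m{k}", str(chromosomes[k]), int(positions[k]),
                     positions[k] / 1e6, *alleles[k])
        for k in range(m)
    ]
    return GenotypeMatrix(samples, markers, calls)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_random_matrix(rng):
    """20 individuals x 120 markers on two chromosomes, 2% missing."""
    p = rng.uniform(0.05, 0.95, 120)
    calls = rng.binomial(2, p, size=(20, 120)).astype(np.int8)
    calls[rng.random(calls.shape) < 0.02] = -1
    chroms = ["1"] * 60 + ["2"] * 60
    pos = list(range(10_000, 610_000, 10_000))[:60] * 2
    return make_matrix(calls, chroms, pos)
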