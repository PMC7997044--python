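import numpy as np
import pytest

from multicd.types import CorrelationMatrix, DomainSolution, GenomicBinning


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def block_correlation(block_sizes, intra, inter=0.0):
    """Dense block-structured correlation matrix with unit diagonal."""
    n = sum(block_sizes)
    C = np.full((n, n), float(inter))
    start = 0
    for b in block_sizes:
        C[start : start + b, start : start + b] = intra
        start += b
    np.fill_diagonal(C, 1.0)
    return C


@pytest.fixture
def two_block_corr():
    """N=8 noiseless two-block correlation (intra 0.8, inter 0)."""
    C = block_correlation([4, 4], 0.8)
    return CorrelationMatrix(C, np.ones(8, dtype=bool), GenomicBinning("chrT", 50_000, 8))


@pytest.fixture
def two_block_labels():
    return DomainSolution(np.array([1, 1, 1, 1, 2, 2, 2, 2]))


def enumerate_partitions(n):
    """All set partitions of n items as restricted-growth label tuples (0-based)."""

    def rec(prefix, mx):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for v in range(mx + 2):
            yield from rec(prefix + [v], max(mx, v))

    yield from rec([], -1)
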