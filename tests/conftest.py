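import numpy as np
import pytest

from rnavote.ensemble import BasePairMatrix
from rnavote.structures import SecondaryStructure


def random_pair_matrix(rng: np.random.Generator, n_range=(5, 13), max_pairs=15) -> BasePairMatrix:
    """Random sparse score matrix (possibly with crossing/conflicting candidates)."""
    n = int(rng.integers(*n_range))
    scores = {}
    for _ in range(int(rng.integers(0, max_pairs + 1))):
        i = int(rng.integers(1, n))
        j = int(rng.integers(i + 1, n + 1))
        scores[(i, j)] = float(rng.uniform(0.05, 1.0))
    return BasePairMatrix(n=n, scores=scores)


def random_valid_structure(rng: np.random.Generator, n: int, n_pairs: int) -> SecondaryStructure:
    """Random structure obeying one-pair-per-base (crossing allowed)."""
    positions = list(rng.permutation(np.arange(1, n + 1)))
    pairs = set()
    while len(pairs) < n_pairs and len(positions) >= 2:
        a, b = positions.pop(), positions.pop()
        pairs.add((min(int(a), int(b)), max(int(a), int(b))))
    return SecondaryStructure(n=n, pairs=frozenset(pairs))


def crossing_oracle(structure: SecondaryStructure) -> bool:
    """Exhaustive O(m^2) pseudoknot check: no (i,j),(k,l) with i<k<j<l."""
    pairs = sorted(structure.pairs)
    for a in range(len(pairs)):
        for b in range(a + 1, len(pairs)):
            (i, j), (k, l) = pairs[a], pairs[b]
            if i < k < j < l:
                return False
    return True


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
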