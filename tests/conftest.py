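import numpy as np
import pytest

from phagehost.network import BipartiteMatrix


def make_bm(cells) -> BipartiteMatrix:
    """BipartiteMatrix from a nested list, with generated labels."""
    A = np.asarray(cells)
    return BipartiteMatrix(
        A=A,
        row_labels=[f"g{i}" for i in range(A.shape[0])],
        col_labels=[f"v{j}" for j in range(A.shape[1])],
    )


def random_bm(rng: np.random.Generator, max_side: int = 8) -> BipartiteMatrix:
    """Random binary matrix with no empty row or column."""
    while True:
        r = int(rng.integers(2, max_side + 1))
        c = int(rng.integers(2, max_side + 1))
        A = (rng.random((r, c)) < rng.uniform(0.2, 0.8)).astype(np.int8)
        if A.sum(axis=1).all() and A.sum(axis=0).all():
            return make_bm(A)


@pytest.fixture
def staircase():
    return make_bm([[1, 1, 1], [1, 1, 0], [1, 0, 0]])
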