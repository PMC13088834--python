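import numpy as np
import pytest

from emanova.io_formats import AbundanceTable, read_newick


@pytest.fixture
def star_tree():
    return read_newick("(A:1,B:1,C:1);")


@pytest.fixture
def caterpillar_tree():
    return read_newick("(A:1,(B:0.5,C:0.5):1);")


@pytest.fixture
def small_table():
    values = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [0.5, 0.5, 0.0],
            [0.25, 0.25, 0.5],
        ]
    )
    return AbundanceTable(values, ["s1", "s2", "s3", "s4"], ["A", "B", "C"])


def centered_random_matrix(n, rng):
    """Random symmetric double-centered matrix."""
    A = rng.standard_normal((n, n))
    A = A + A.T
    A -= A.mean(axis=0)[None, :]
    A -= A.mean(axis=1)[:, None]
    A += A.mean()
    return 0.5 * (A + A.T)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
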