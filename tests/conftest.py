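import numpy as np
import pandas as pd
import pytest

from mnda.io import AbundanceTable
from mnda.multiplex import MultiplexNetwork


@pytest.fixture
def toy_table():
    """4 individuals x 2 time points x 3 taxa with simple counts."""
    counts = pd.DataFrame(
        [
            [10, 0, 5],
            [8, 2, 4],
            [12, 1, 0],
            [9, 3, 6],
            [11, 0, 7],
            [7, 4, 3],
            [10, 2, 2],
            [8, 1, 5],
        ],
        index=[f"i{k}_t{t}" for t in (1, 2) for k in range(4)],
        columns=["taxA", "taxB", "taxC"],
    )
    metadata = pd.DataFrame(
        {
            "individual_id": [f"i{k}" for _ in (1, 2) for k in range(4)],
            "time_point": ["t1"] * 4 + ["t2"] * 4,
            "phenotype": [0, 0, 1, 1] * 2,
        },
        index=counts.index,
    )
    return AbundanceTable(counts, metadata)


@pytest.fixture
def path_multiplex():
    """Path a-b-c with unit weights, two identical layers."""
    w = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
    return MultiplexNetwork(["a", "b", "c"], [w, w.copy()], ["t1", "t2"], owner="toy")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_weighted_graph(rng, k=8, p=0.5):
    """Random symmetric weighted adjacency with zero diagonal."""
    w = rng.uniform(0.1, 1.0, size=(k, k)) * (rng.random((k, k)) < p)
    w = np.triu(w, 1)
    w = w + w.T
    return w
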