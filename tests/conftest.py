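import numpy as np
import pandas as pd
import pytest

from nichecomm import CellAnnotation, CountMatrix, LRPairTable, log_normalize


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 genes x 4 cells with one mitochondrial gene."""
    values = np.array(
        [
            [2, 0, 5, 1],
            [0, 0, 3, 1],
            [1, 0, 2, 2],  # mt-Co2
        ]
    )
    return CountMatrix(values, ["g1", "g2", "mt-Co2"], ["c1", "c2", "c3", "c4"])


@pytest.fixture
def tiny_annotation() -> CellAnnotation:
    table = pd.DataFrame(
        {
            "cell_type": ["microglia", "microglia", "NSPC", "NSPC"],
            "time_point": ["uninjured", "PT_D1", "uninjured", "PT_D1"],
        },
        index=pd.Index(["c1", "c2", "c3", "c4"], name="cell_id"),
    )
    return CellAnnotation(table)


@pytest.fixture
def small_pairs() -> LRPairTable:
    return LRPairTable(pd.DataFrame({"ligand": ["g1"], "receptor": ["g2"]}))


def make_norm(values: np.ndarray, gene_ids=None, cell_ids=None, scale: float = 10_000.0):
    """Log-normalize an arbitrary integer matrix for tests."""
    values = np.asarray(values)
    genes = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    cells = cell_ids or [f"c{j}" for j in range(values.shape[1])]
    return log_normalize(CountMatrix(values, genes, cells), scale)
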