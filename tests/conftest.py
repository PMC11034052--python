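import numpy as np
import pytest

from clonegan import CNMatrix, ExprMatrix, ProcessedMatrix


@pytest.fixture
def small_cn() -> CNMatrix:
    values = np.array(
        [
            [2, 2, 4, 1, 0],
            [2, 2, 4, 3, 2],
            [1, 2, 2, 3, 2],
        ],
        dtype=float,
    )
    return CNMatrix(
        values=values,
        cell_ids=["c1", "c2", "c3"],
        bin_ids=[f"bin{j}" for j in range(5)],
    )


@pytest.fixture
def small_expr() -> ExprMatrix:
    counts = np.array(
        [
            [100, 0, 50],
            [150, 150, 0],
            [10, 20, 30],
        ]
    )
    return ExprMatrix(
        counts=counts,
        cell_ids=["r1", "r2", "r3"],
        gene_ids=["g1", "g2", "g3"],
    )


def processed(values, cell_prefix="c", feat_prefix="f") -> ProcessedMatrix:
    values = np.asarray(values, dtype=float)
    return ProcessedMatrix(
        values=values,
        cell_ids=[f"{cell_prefix}{i}" for i in range(values.shape[0])],
        feature_ids=[f"{feat_prefix}{j}" for j in range(values.shape[1])],
    )
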