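import numpy as np
import pytest

from igisplus import LabeledExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_matrix():
    """3 samples x 2 genes, binary labels — the smallest legal dataset."""
    return LabeledExpressionMatrix(
        values=[[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]],
        gene_ids=["gA", "gB"],
        labels=[0, 0, 1, 1],
    )


def perfect_gene_data(m=24, n_noise=6, seed=0):
    """One gene that linearly separates two classes, the rest noise."""
    rng = np.random.default_rng(seed)
    labels = np.repeat([0, 1], m // 2)
    values = rng.standard_normal((m, n_noise + 1))
    values[:, 0] = labels * 10.0 + rng.normal(0, 0.1, m)
    return LabeledExpressionMatrix(
        values=values, gene_ids=[f"g{i}" for i in range(n_noise + 1)], labels=labels
    )
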