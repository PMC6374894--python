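import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def tiny_matrix():
    """3 genes x 2 samples with a clean ordering."""
    return pd.DataFrame(
        [[10.0, 20.0], [5.0, 8.0], [1.0, 2.0]],
        index=["A", "B", "C"],
        columns=["s1", "s2"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


def make_ordered_matrix(n_genes: int, n_samples: int) -> pd.DataFrame:
    """Every sample ranks the genes identically (gene 0 highest)."""
    values = np.arange(n_genes, 0, -1, dtype=float)[:, None] * np.ones((1, n_samples))
    return pd.DataFrame(
        values,
        index=[f"G{i:03d}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
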