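import numpy as np
import pandas as pd
import pytest

from telostrat import GeneSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_expression(rng):
    """50 genes x 10 samples, positive continuous values."""
    genes = [f"g{i:03d}" for i in range(50)]
    samples = [f"s{j}" for j in range(10)]
    values = rng.lognormal(mean=2.0, sigma=0.8, size=(50, 10))
    return pd.DataFrame(values, index=genes, columns=samples)


@pytest.fixture
def small_gene_set(small_expression, rng):
    genes = tuple(rng.choice(small_expression.index, size=8, replace=False))
    return GeneSet(name="sig8", genes=genes)
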