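import numpy as np
import pandas as pd
import pytest

from pathdriver.activity import RESISTANT, SENSITIVE, ResponseLabels
from pathdriver.io import ExpressionMatrix


def make_labels(n_sensitive: int, n_resistant: int, prefix: str = "S") -> ResponseLabels:
    ids = [f"{prefix}{i}" for i in range(n_sensitive + n_resistant)]
    vals = [SENSITIVE] * n_sensitive + [RESISTANT] * n_resistant
    return ResponseLabels(pd.Series(vals, index=ids, name="label"))


def make_expr(values: np.ndarray, prefix: str = "S", gene_prefix: str = "G") -> ExpressionMatrix:
    g, n = values.shape
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"{gene_prefix}{i}" for i in range(g)],
            columns=[f"{prefix}{j}" for j in range(n)],
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_bundle():
    """Small planted dataset shared by pipeline-level tests."""
    from pathdriver.simulate import SyntheticSpec, generate_dataset

    spec = SyntheticSpec(
        n_samples=80, n_genes=300, n_pathways=10, effect_delta=2.0, seed=11
    )
    return generate_dataset(spec)
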