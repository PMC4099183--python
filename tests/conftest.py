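import numpy as np
import pandas as pd
import pytest

from anni import AnniConfig, ExpressionMatrix, SyntheticSpec, generate_dataset, minmax_scale


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    """3 samples x 2 genes, unscaled."""
    df = pd.DataFrame(
        {"GENEA": [0.0, 5.0, 10.0], "GENEB": [7.0, 7.0, 7.0]},
        index=["s1", "s2", "s3"],
    )
    return ExpressionMatrix(df)


@pytest.fixture
def small_panel():
    """Scaled 40-sample, 8-gene panel with a 3-gene correlated block."""
    spec = SyntheticSpec(
        n_samples=40, n_features=8, n_correlated=3, n_predictive=2, seed=11
    )
    m, truth = generate_dataset(spec)
    return minmax_scale(m), truth


@pytest.fixture
def fast_cfg():
    """Small-but-real training configuration for quick end-to-end runs."""
    return AnniConfig(n_reshuffles=2, n_repeats=1, epochs=60, rng_seed=5)


def random_expression(rng, n_samples=10, n_genes=4) -> ExpressionMatrix:
    df = pd.DataFrame(
        rng.normal(size=(n_samples, n_genes)),
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"g{j}" for j in range(n_genes)],
    )
    return ExpressionMatrix(df)
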