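import numpy as np
import pandas as pd
import pytest

from lncmetnet import ExpressionMatrix, SimulationConfig, simulate_expression


@pytest.fixture
def small_config():
    """A quick-to-simulate design: 10 lncRNAs, 30 protein-coding genes,
    one 8-gene module, 20 tumor/normal pairs."""
    return SimulationConfig(
        n_lncrna=10,
        n_pcg=30,
        n_pairs=20,
        de_fraction=0.1,
        log2_effect=2.0,
        noise_sd=0.5,
        n_modules=1,
        module_size=8,
        module_corr=0.8,
        n_go_terms=6,
        go_background_rate=0.3,
        mirna_count=4,
        seed=7,
    )


@pytest.fixture
def small_dataset(small_config):
    return simulate_expression(small_config)


def make_matrix(values, groups=None, pairs=None, biotypes=None):
    """Assemble an ExpressionMatrix from a plain dict/array of log2 values."""
    df = pd.DataFrame(values)
    n = df.shape[1]
    if groups is None:
        groups = ["tumor" if i % 2 == 0 else "normal" for i in range(n)]
    if pairs is None:
        pairs = [f"P{i // 2}" for i in range(n)]
    if biotypes is None:
        biotypes = ["protein_coding"] * df.shape[0]
    return ExpressionMatrix(
        values=df,
        sample_group=pd.Series(groups, index=df.columns),
        pair_id=pd.Series(pairs, index=df.columns),
        biotype=pd.Series(biotypes, index=df.index),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
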