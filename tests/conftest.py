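import numpy as np
import pytest

from coexmux.confignull import fit_configuration_model
from coexmux.layers import ExpressionLayer, build_multilayer
from coexmux.synth import SyntheticParams, planted_multilayer_expression


def random_correlation(n, n_obs=None, seed=0):
    """Empirical correlation matrix of Gaussian draws (PD for n_obs > n)."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, n_obs or (2 * n + 5)))
    return np.corrcoef(x)


@pytest.fixture(scope="session")
def small_dataset():
    """Two-layer, 16-gene planted dataset: one generalist block, one
    specialist block, fast enough for per-test use."""
    params = SyntheticParams(
        layer_names=("pancreas", "skin"),
        n_genes=16,
        generalist_blocks=(5,),
        specialist_block=4,
        samples_per_layer=150,
        donor_overlap=0.5,
    )
    return planted_multilayer_expression(params, seed=123)


@pytest.fixture(scope="session")
def small_mlc(small_dataset):
    return build_multilayer(small_dataset.layers)


@pytest.fixture(scope="session")
def small_nulls(small_mlc):
    return [
        fit_configuration_model(small_mlc.rho[a], layer_name=name)
        for a, name in enumerate(small_mlc.layer_names)
    ]


@pytest.fixture
def toy_layer():
    """Tiny deterministic expression layer for exact-value tests."""
    values = np.array(
        [
            [0.0, 1.0, 3.0, 7.0],
            [1.0, 3.0, 7.0, 15.0],
            [5.0, 2.0, 9.0, 0.0],
            [2.0, 2.0, 2.0, 8.0],
        ]
    )
    return ExpressionLayer(
        layer_name="pancreas",
        gene_ids=["gA", "gB", "gC", "gD"],
        sample_ids=["s1", "s2", "s3", "s4"],
        donor_ids=["d1", "d2", "d3", "d4"],
        values=values,
    )
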