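import numpy as np
import pytest

from cgmi.composite import build_composite
from cgmi.synthetic_data import SyntheticConfig, generate_plots
from cgmi.vegindex import compute_all


@pytest.fixture(scope="session")
def default_plots():
    """One default synthetic plot table (66 plots, seed 0)."""
    return generate_plots(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def default_indices(default_plots):
    return compute_all(default_plots)


@pytest.fixture(scope="session")
def default_composite(default_plots):
    table, weights, bounds = build_composite(default_plots)
    return table, weights, bounds


@pytest.fixture()
def noise_free_config():
    """All indicator and band noise switched off: indicators are exact
    affine images of the latent vigor factor."""
    cfg = SyntheticConfig(seed=1)
    return cfg.replace(
        noise_sd={k: 0.0 for k in cfg.noise_sd},
        reflectance_params={
            band: (base, slope, 0.0)
            for band, (base, slope, _sd) in cfg.reflectance_params.items()
        },
    )


@pytest.fixture(scope="session")
def linear_regression_data():
    """Noise-free y = 3 x1 - 2 x2 + 1 on random features."""
    rng = np.random.default_rng(42)
    X = rng.uniform(0, 1, size=(40, 2))
    y = 3.0 * X[:, 0] - 2.0 * X[:, 1] + 1.0
    return X, y
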