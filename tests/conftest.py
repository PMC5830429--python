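import numpy as np
import pytest

import chancap as cc


@pytest.fixture(scope="session")
def small_population():
    """A 12-cell synthetic study with default (paper-like) conditions."""
    cfg = cc.SimulationConfig(n_cells=12, seed=101)
    peaks, truth = cc.generate_peak_table(cfg)
    return cfg, peaks, truth


@pytest.fixture(scope="session")
def fitted_noise(small_population):
    _, peaks, _ = small_population
    return cc.fit_noise_params(peaks, min_n=20)


@pytest.fixture(scope="session")
def quiet_config():
    """Nearly noise-free configuration: deterministic responses."""
    return cc.SimulationConfig(
        n_cells=4, seed=5, sigma=(1e-12,) * 7, nu=(10.0,) * 7, desensitization_rate=1.0
    )


def make_two_input_channel(delta, sigma=0.2, nu=5.0, grid_points=None):
    """Symmetric binary scaled-t channel with mean separation ``delta``."""
    return cc.build_channel(
        np.array([100.0, 1000.0]),
        np.array([0.0, delta]),
        np.array([sigma, sigma]),
        np.array([nu, nu]),
        grid_points=grid_points,
    )
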