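import numpy as np
import pytest

from blogitfe import DGPConfig, PanelDataset, simulate_binomial_panel


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def tiny_panel():
    """Hand-built 3-unit panel, K=2, T=2, one covariate."""
    return PanelDataset(
        unit_ids=np.repeat(["a", "b", "c"], 2),
        time_ids=np.tile([1, 2], 3),
        K=2,
        Y=np.array([0, 0, 1, 2, 2, 2]),  # a: total 0; b: interior; c: total K*T
        X=np.array([0.0, 1.0, -0.5, 0.5, 0.3, 0.6]),
        covariate_names=["x"],
    )


@pytest.fixture
def small_sim():
    """A modest simulated binomial panel for fitting tests."""
    sim = simulate_binomial_panel(DGPConfig(N=60, T=3, K=3), seed=11)
    return sim


def random_informative_group(rng, K_max=3, T_max=4):
    """Random (eta, Y, K) with an interior group total."""
    K = int(rng.integers(1, K_max + 1))
    T = int(rng.integers(2, T_max + 1))
    eta = rng.normal(0.0, 2.0, T)
    while True:
        Y = rng.integers(0, K + 1, T)
        if 0 < Y.sum() < K * T:
            return eta, Y, K
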