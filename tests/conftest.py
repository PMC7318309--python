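import numpy as np
import pytest

from piurkit import MixtureSpec, SimulationConfig, simulate_panel


@pytest.fixture(scope="session")
def null_panel_50():
    """m=1000, n=100, true overall IUR 0.50, no outliers."""
    return simulate_panel(SimulationConfig(m=1000, target_iur=0.5, seed=101))


@pytest.fixture(scope="session")
def contaminated_panel_25():
    """m=1000, n=100, true IUR 0.25, 5% outliers at 4 sigma_T."""
    cfg = SimulationConfig(
        m=1000, target_iur=0.25, mix=MixtureSpec(pi1=0.05, gamma=4.0), seed=202
    )
    return simulate_panel(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
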