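import numpy as np
import pytest

from fccskit.correlation import CorrelationCurve
from fccskit.synthetic import SimulationParams, simulate_ffs_traces


def make_lag_grid(start=1e-6, stop=2.0, num=220):
    """Log lag grid spanning the amplitude and offset windows."""
    return np.geomspace(start, stop, num)


@pytest.fixture(scope="session")
def lag_grid():
    return make_lag_grid()


@pytest.fixture(scope="session")
def small_sim_traces():
    """One cheap simulated single-species trace pair, reused across tests."""
    params = SimulationParams(
        conc_green=30.0,
        d_green=1e-7,
        omega0_g=0.25,
        z0_g=0.375,
        omega0_r=0.25,
        z0_r=0.375,
        bin_width=2e-5,
        duration=1.0,
        n_traces=1,
        box_size=3.0,
        dark_rate=500.0,
        seed=42,
    )
    return params, simulate_ffs_traces(params)[0]


def flat_curve(value=0.0, pair="GG"):
    lags = make_lag_grid()
    return CorrelationCurve(lags, np.full(lags.shape, value), channel_pair=pair)
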