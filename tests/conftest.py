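import numpy as np
import pytest

from ricewcm import parcel_b_config, parcel_cde_config, simulate_plots


# fitted-model truths used across tests: mature parcel and grouting-stage parcel
CURVE_B = {"C": -10.57, "a": -1.58, "b": 0.6638}
CURVE_CDE = {"C": -15.44, "a": -1.203, "b": 0.4669}
EAR_CAL_B = {"slope": 2.5404, "intercept": 0.2943}
GRAIN_CAL_B = {"slope": 78315.0, "intercept": 5015.5}
STEMLEAF_B = {"p": 4.4297, "q": 0.1408}
STEMLEAF_CDE = {"p": 3.2385, "q": 1.255}


def curve_forward(x, C, a, b):
    """Reference saturating curve, written independently of the package."""
    return C - np.exp(-(np.asarray(x, dtype=float) - a) / b)


@pytest.fixture(scope="session")
def b_config():
    return parcel_b_config(seed=11)


@pytest.fixture(scope="session")
def cde_config():
    return parcel_cde_config(seed=12)


@pytest.fixture(scope="session")
def b_plots(b_config):
    return simulate_plots(b_config)


@pytest.fixture(scope="session")
def noise_free_plots(b_config):
    return simulate_plots(b_config.noise_free())
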