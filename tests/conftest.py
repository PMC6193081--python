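"""Shared fixtures.

Expensive default-parameter trajectories are session-scoped and computed
once; tests that need custom parameters integrate their own (usually over a
shorter horizon).
"""

import numpy as np
import pytest

from hiis import appired_ii_protocol, integrate, placebo_protocol
from hiis.model import ModelParameters
from hiis.synth import SynthConfig, generate_clinical_series


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def biap_protocol():
    return appired_ii_protocol()


@pytest.fixture(scope="session")
def placebo():
    return placebo_protocol()


@pytest.fixture(scope="session")
def biap_trajectory(params, biap_protocol):
    return integrate(params, biap_protocol)


@pytest.fixture(scope="session")
def placebo_trajectory(params, placebo):
    return integrate(params, placebo)


@pytest.fixture(scope="session")
def homeostatic_trajectory(params, placebo):
    quiet = params.with_updates(itm_insult=0.0)
    return integrate(quiet, placebo)


@pytest.fixture(scope="session")
def noiseless_series(params):
    cfg = SynthConfig(params=params, noise_frac=0.0)
    return cfg, generate_clinical_series(cfg)


@pytest.fixture(scope="session")
def noisy_series(params):
    cfg = SynthConfig(params=params, seed=2018)
    return cfg, generate_clinical_series(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
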