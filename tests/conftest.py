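import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from delaysir import ModelParameters

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def det_params():
    """Deterministic scenario family (strong vaccination, weak vertical path)."""
    return ModelParameters(
        beta=0.4, b=0.3, p=0.1, m=0.9, alpha1=0.6, alpha2=0.1,
        gamma=0.2, omega=1.0, sigma=0.0,
    )


@pytest.fixture
def sto_params():
    """Stochastic scenario family: sub-threshold extinction regime."""
    return ModelParameters(
        beta=0.4, b=0.3, p=0.5, m=0.2, alpha1=0.6, alpha2=0.1,
        gamma=0.2, omega=1.0, sigma=0.5,
    )


@pytest.fixture
def persistent_params(sto_params):
    """Stronger transmission, weak noise: persistent-in-the-mean regime."""
    return dataclasses.replace(sto_params, beta=0.8, sigma=0.2)
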