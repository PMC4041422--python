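import numpy as np
import pytest
from hypothesis import settings

from stopflow import BindingSystem, default_signal_model, rate_lookup

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def frt_irp1_rates():
    return rate_lookup(("FRT", "IRP1"), 0.0)


@pytest.fixture(scope="session")
def aco2_irp1_rates():
    return rate_lookup(("ACO2", "IRP1"), 0.0)


@pytest.fixture(scope="session")
def frt_eif4f_rates():
    return rate_lookup(("FRT", "eIF4F"), 0.0)


@pytest.fixture
def frt_system(frt_irp1_rates):
    """Standard association mix: 0.05 uM labeled RNA + 1 uM IRP1."""
    return BindingSystem.single(0.05, 1.0, frt_irp1_rates, name="IRP1")


@pytest.fixture
def noiseless_anisotropy():
    return default_signal_model("anisotropy", noise_sd=0.0)


@pytest.fixture
def noiseless_fluorescence():
    return default_signal_model("fluorescence", noise_sd=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
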