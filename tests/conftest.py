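import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import aobflux as af
from aobflux.synthetic import ExperimentConfig, parametric_generate

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def aob_model():
    return af.default_aob_model()


@pytest.fixture(scope="session")
def const():
    return af.IsotopeConstants()


@pytest.fixture(scope="session")
def setup():
    return af.LabelingSetup()


@pytest.fixture(scope="session")
def truth_fit():
    """Ground-truth empirical fits of the default 98%-label experiment."""
    return (af.FirstOrderFit(c0=0.1, c1=6.0, lam=0.04),
            af.LogisticFit(d0=-25.0, d1=80.0, d2=80.0, k=0.08))


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free default (98 atom% label) parametric experiment."""
    cfg = ExperimentConfig(noise_conc=0, noise_delta=0, noise_sulfide=0, seed=0)
    ts, truth = parametric_generate(cfg)
    return ts, truth
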