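import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

from periseg.phantom import PhantomSpec, generate_phantom, generate_corpus


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, gradient-free 3-tooth phantom with one lesion."""
    spec = PhantomSpec(n_teeth=3, roots_per_tooth=[1, 2, 2],
                       lesion_flags=[False, False, True],
                       noise_sd=0.0, illumination_slope=0.0, seed=11)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def default_corpus():
    """Small default-condition corpus shared by the slower tests."""
    return generate_corpus(30, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
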