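import numpy as np
import pytest

from cvrconcord import phantom, pipeline

SMALL_SHAPE = (20, 20, 16)


@pytest.fixture(scope="session")
def default_subject():
    """Phantom at the standard study conditions (noise 20% of amplitude)."""
    return phantom.simulate_subject(phantom.PhantomSpec(shape=SMALL_SHAPE, seed=7))


@pytest.fixture(scope="session")
def noiseless_subject():
    return phantom.simulate_subject(
        phantom.PhantomSpec(shape=SMALL_SHAPE, noise_sd=0.0, seed=11)
    )


@pytest.fixture(scope="session")
def default_result(default_subject):
    """Full pipeline output for the default phantom."""
    return pipeline.analyze_subject(default_subject)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
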