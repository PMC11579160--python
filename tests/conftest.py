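import numpy as np
import pytest

from uroseg import phantom


@pytest.fixture(scope="session")
def straight_case():
    """Default phantom: no tilt, no curvature, 1 x 1 x 2 mm grid."""
    return phantom.generate_phantom(phantom.PhantomParams())


@pytest.fixture(scope="session")
def tilted_case():
    params = phantom.PhantomParams(urethra_tilt_deg=20.0,
                                   urethra_curvature=0.2)
    return phantom.generate_phantom(params)


@pytest.fixture(scope="session")
def small_population():
    return phantom.sample_population(10, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
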