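import numpy as np
import pytest

from shearkad import PhantomSpec, build_filterbank, make_natural_test_image, make_phantom


@pytest.fixture(scope="session")
def bank64():
    return build_filterbank((64, 64), 3, (8, 8, 4))


@pytest.fixture(scope="session")
def phantom128():
    return make_phantom(PhantomSpec(size=128))


@pytest.fixture(scope="session")
def textured128():
    return make_natural_test_image(size=128, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
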