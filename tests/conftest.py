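import warnings

import numpy as np
import pytest

from axonfield import RasterImage, basis_responses, build_filter_bank

warnings.filterwarnings("ignore", message="Mean of empty slice")
warnings.filterwarnings("ignore", message="Degrees of freedom")


@pytest.fixture(scope="session")
def unit_bank():
    """G2 bank at the standard 1.8 um scale on a 1 um pixel grid."""
    return build_filter_bank(1.8, 1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def random_basis():
    """Basis responses of a fixed random texture image."""
    gen = np.random.default_rng(7)
    img = RasterImage(gen.random((48, 48)) * 10.0, 1.0)
    return img, basis_responses(img, build_filter_bank(1.8, 1.0))
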