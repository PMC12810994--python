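import numpy as np
import pytest

from aneuprep import ScaleSpaceParams, Volume3D, make_case, tube_only


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_volume(rng):
    return Volume3D(data=rng.random((12, 10, 9)), spacing=(0.7, 0.9, 1.1))


@pytest.fixture(scope="session")
def tube_case():
    """Noiseless single-tube phantom shared by read-only tests."""
    spec = tube_only(seed=7)
    spec.noise_sigma = 0.0
    return make_case(spec)


@pytest.fixture(scope="session")
def noisy_tube_case():
    return make_case(tube_only(seed=7))


@pytest.fixture(scope="session")
def fast_scale_params():
    """Two scales keep filter-heavy tests quick without changing semantics."""
    return ScaleSpaceParams(scales_mm=(1.0, 2.0))
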