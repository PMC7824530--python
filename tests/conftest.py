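import numpy as np
import pytest

from picgan.phantom import MaskConfig, PhantomSpec, make_sample


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sample():
    """One noiseless 32x32, 4-coil sample with an AF-2 random mask."""
    return make_sample(
        PhantomSpec(size=(32, 32), n_coils=4, seed=7),
        MaskConfig(kind="random", af=2.0, acs_lines=8, seed=7),
    )


@pytest.fixture(scope="session")
def full_sample():
    """Fully sampled (AF=1) noiseless 32x32, 4-coil sample."""
    return make_sample(
        PhantomSpec(size=(32, 32), n_coils=4, seed=11),
        MaskConfig(kind="regular", af=1.0, acs_lines=0),
    )
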