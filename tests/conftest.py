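import numpy as np
import pytest

from udrwm import PhantomSpec, make_atlas, simulate_cohort


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(grid=(16, 20, 16), n_regions=3, n_latents=2, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return simulate_cohort(small_spec, 12)


@pytest.fixture(scope="session")
def small_atlas(small_spec):
    mask, atlas = make_atlas(small_spec)
    return mask, atlas


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
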