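import numpy as np
import pytest

import pbmap


@pytest.fixture(scope="session")
def noiseless_spec():
    return pbmap.PhantomSpec(height=48, width=48, seed=7, shot_noise_scale=0.0,
                             read_noise_sd=0.0, bit_depth=None,
                             defect_fraction=0.0, param_smoothing_sigma=1.0)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_spec):
    return pbmap.generate_phantom(noiseless_spec)


@pytest.fixture(scope="session")
def noiseless_maps(noiseless_phantom):
    stack, _ = noiseless_phantom
    return pbmap.fit_stack(stack)


@pytest.fixture(scope="session")
def noisy_spec():
    # default acquisition conditions at reduced size: 8-bit, shot + read noise
    return pbmap.PhantomSpec(height=64, width=64, seed=11)


@pytest.fixture(scope="session")
def noisy_phantom(noisy_spec):
    return pbmap.generate_phantom(noisy_spec)


@pytest.fixture(scope="session")
def noisy_maps(noisy_phantom):
    stack, _ = noisy_phantom
    return pbmap.fit_stack(stack)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
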