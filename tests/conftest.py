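import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_eye():
    """A distractor-free synthetic eye with realistic sensor noise."""
    from pupilfcm import EyeSpec, generate_eye

    return generate_eye(
        EyeSpec(noise_sd=3.0, gradient_amplitude=10.0, glints=(), n_lashes=0, seed=7)
    )
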