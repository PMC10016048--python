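import numpy as np
import pytest

from mobidt.montage import get_biosemi64
from mobidt.synthetic import NoiseSpec, default_templates, gen_epoch_set


@pytest.fixture(scope="session")
def montage():
    names, pos = get_biosemi64()
    return names, pos


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noisy_cr_epochs():
    """60 stimulus-locked epochs with realistic pink+white noise, 128 Hz."""
    return gen_epoch_set(
        default_templates("stimulus_onset"),
        60,
        "stimulus_onset",
        "correct_rejection",
        noise=NoiseSpec(pink_sd_uv=5.0, white_sd_uv=4.0),
        sfreq=128.0,
        seed=77,
    )
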