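import numpy as np
import pytest

from stepshape.synthkin import SynthConfig, generate_dataset
from stepshape.taskspace import LimbModel


@pytest.fixture(scope="session")
def limb():
    return LimbModel(hip_z_m=0.90, thigh_l_m=0.40, shank_l_m=0.42)


@pytest.fixture(scope="session")
def clean_config():
    """One participant, one block per height, no noise of any kind."""
    return SynthConfig(
        n_participants=1,
        blocks_per_height=1,
        angle_noise_sd_deg=0.0,
        peak_config_sd_deg=0.0,
        participant_clearing_sd_m=0.0,
        jump_prob=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    return generate_dataset(clean_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
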