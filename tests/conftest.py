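import numpy as np
import pytest

from vestkin.simulate import SyntheticTrialSpec, generate_trial


def noise_free_spec(**kwargs) -> SyntheticTrialSpec:
    """Spec with every stochastic corruption disabled."""
    defaults = dict(
        condition="standing_LR",
        head_rom_true=45.0,
        oscillation_freq=0.5,
        gyro_noise_sd=0.0,
        gyro_bias=0.0,
        accel_noise_sd=0.0,
        mag_noise_sd=0.0,
        soft_tissue_amp=0.0,
        occlusion_at_turns=False,
    )
    defaults.update(kwargs)
    return SyntheticTrialSpec(**defaults)


@pytest.fixture(scope="session")
def clean_standing_trial():
    """One noise-free standing left/right trial, shared across tests."""
    spec = noise_free_spec()
    return (*generate_trial(spec), spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
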