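import numpy as np
import pytest

from ebcap.synthetic import SyntheticConfig, generate_track


@pytest.fixture(scope="session")
def noiseless_config() -> SyntheticConfig:
    """A single-speed, noise-free condition for exact round-trip checks."""
    return SyntheticConfig(
        n_tracks=1,
        vg_mean=28.0,
        vg_sd=1e-9,
        vg_lo=27.0,
        vg_hi=29.0,
        cap_scale_sd=0.0,
        f_crit=0.2,
        vs_resid_sd=0.0,
        pos_noise_sd=0.0,
        intensity_cv=0.0,
        bg_noise_sd=0.0,
        orientation_jitter=0.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def noiseless_track(noiseless_config):
    rng = np.random.default_rng(1)
    return generate_track(noiseless_config, rng)
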