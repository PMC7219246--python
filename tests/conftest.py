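import numpy as np
import pytest

from nirslat.core import (
    CHROMOPHORES,
    HBO,
    HBR,
    Trial,
    default_montage,
    trial_n_samples,
)
from nirslat.synth import SynthParams, generate_session

FS = 7.8125
DEFAULT_PAIRS = [(2, 12), (7, 17), (8, 18)]


@pytest.fixture(scope="session")
def montage():
    return default_montage()


def make_trial(
    values=None, hand="right", condition="execution", fs=FS, channels=range(1, 21)
):
    """Build a trial with per-(channel, chromophore) constant or array values.

    ``values`` maps (channel, chromophore) -> scalar or array; unlisted
    series default to zero.
    """
    n = trial_n_samples(fs)
    data = {}
    for ch in channels:
        for chrom in CHROMOPHORES:
            v = (values or {}).get((ch, chrom), 0.0)
            arr = np.full(n, float(v)) if np.isscalar(v) else np.asarray(v, float)
            data[(ch, chrom)] = arr
    return Trial(hand=hand, condition=condition, fs=fs, data=data)


@pytest.fixture
def zero_trial():
    return make_trial()


@pytest.fixture(scope="session")
def clean_exec_recording():
    """Noise-free execution session, 5 trials per hand."""
    from nirslat.synth import NoiseParams

    params = SynthParams(
        seed=0,
        noise=NoiseParams(
            mayer_amp=0, resp_amp=0, cardiac_amp=0, white_sigma=0, drift_slope=0
        ),
    )
    return generate_session(params, "execution", ["right", "left"] * 5)


@pytest.fixture(scope="session")
def noisy_exec_recording():
    """Default-noise execution session at SNR 3, 10 trials per hand."""
    params = SynthParams(seed=7).with_snr(3.0, "execution")
    return generate_session(params, "execution", ["right", "left"] * 10)
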