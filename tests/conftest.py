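import numpy as np
import pytest

from erdpipe.io.recording import epoch_trials
from erdpipe.synthetic import CohortSpec, simulate_session


@pytest.fixture(scope="session")
def noiseless_spec():
    """Generator spec with every noise source silenced."""
    return CohortSpec(pink_amp_uv=0.0, white_amp_uv=0.0, emg_noise_uv=0.0,
                      sigma_eps=0.0, sigma_out=0.0, sd_b0=0.0, sd_b1=0.0)


@pytest.fixture(scope="session")
def default_spec():
    return CohortSpec()


def make_session(spec, target, n_trials=10, seed=0, lesion_side="left"):
    rng = np.random.default_rng(seed)
    if np.isscalar(target):
        target = {"left": float(target), "right": float(target)}
    return simulate_session(spec, "S00", 0, target, lesion_side, rng,
                            n_trials=n_trials)


@pytest.fixture(scope="session")
def noiseless_trials(noiseless_spec):
    """10 noiseless trials at target ERD -50% on both hemispheres."""
    rec = make_session(noiseless_spec, -50.0, n_trials=10, seed=11)
    return epoch_trials(rec)
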