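import numpy as np
import pandas as pd
import pytest

import alphasel as a


@pytest.fixture(scope="session")
def montage():
    return a.make_montage()


@pytest.fixture(scope="session")
def family250():
    return a.build_wavelet_family(sfreq=250.0)


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale simulation settings used by several suites."""
    return a.SimConfig(
        n_participants=2, n_objects=12, reps_per_object=2, sfreq_native=250.0, seed=7
    )


@pytest.fixture(scope="session")
def small_participant(small_cfg, montage):
    epochs, behavior = a.generate_participant(small_cfg, 0, montage)
    return epochs, behavior


def make_tfrset(power, times, freqs, ch_names=None, trial_info=None, units="raw", sfreq=250.0):
    """Hand-assembled TFRSet for unit tests."""
    power = np.asarray(power, dtype=float)
    n_trials, n_ch = power.shape[:2]
    if ch_names is None:
        ch_names = [f"CH{i}" for i in range(n_ch)]
    if trial_info is None:
        trial_info = pd.DataFrame({"participant_id": np.zeros(n_trials, dtype=int)})
    return a.TFRSet(
        power=power,
        times=np.asarray(times, dtype=float),
        frequencies=np.asarray(freqs, dtype=float),
        sfreq=sfreq,
        channel_names=list(ch_names),
        trial_info=trial_info,
    )
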