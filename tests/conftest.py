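import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mibci

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def montage9():
    """A compact 9-electrode montage around the sensorimotor strip."""
    return mibci.montage_from_names(
        ["F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4"])


@pytest.fixture(scope="session")
def small_session(montage9):
    """A strongly separable 3-run session (desk scale)."""
    cfg = mibci.SynthEegConfig(n_series=3, trials_per_task=2, erd_depth=0.6,
                               snr=6.0, seed=11)
    return mibci.generate_mi_session(cfg, montage9)


@pytest.fixture(scope="session")
def small_windows(small_session):
    ws = mibci.epoch_and_window(mibci.bandpass_fir(small_session))
    ws, _ = mibci.reject_outlier_windows(ws)
    return ws


@pytest.fixture(scope="session")
def small_model(small_windows):
    return mibci.fit_decoder(small_windows)


@pytest.fixture(scope="session")
def protocol_session():
    """The full competence-test operating point: 9 series, 6 trials/task,
    19 channels, 256 Hz, erd_depth 0.4, snr 4, seed 1."""
    cfg = mibci.SynthEegConfig(n_series=9, trials_per_task=6, erd_depth=0.4,
                               snr=4.0, sampling_rate=256.0, seed=1)
    return mibci.generate_mi_session(cfg, mibci.standard_montage(19))


@pytest.fixture(scope="session")
def protocol_windows(protocol_session):
    ws = mibci.epoch_and_window(mibci.bandpass_fir(protocol_session))
    ws, _ = mibci.reject_outlier_windows(ws)
    return ws


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
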