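import numpy as np
import pytest

from pceeg import design, synth


@pytest.fixture(scope="session")
def montage44():
    return synth.make_montage(4, 4)


@pytest.fixture(scope="session")
def montage22():
    return synth.make_montage(2, 2)


@pytest.fixture(scope="session")
def schedule50():
    return design.build_trial_schedule(50, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_epochs(data, srate=250.0, t0_ms=None, lock="stimulus", schedule_ref=None,
                channel_names=None):
    """Construct an EpochsSet around a raw (trials, channels, samples) array."""
    data = np.asarray(data, dtype=float)
    n_trials, n_ch, n_t = data.shape
    dt = 1000.0 / srate
    if t0_ms is None:
        t0_ms = 0.0
    times = t0_ms + np.arange(n_t) * dt
    if schedule_ref is None:
        schedule_ref = np.arange(n_trials)
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(n_ch))
    return synth.EpochsSet(
        data=data, srate=srate, times=times, lock=lock, subject_id="test",
        schedule_ref=np.asarray(schedule_ref), channel_names=channel_names,
    )
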