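import numpy as np
import pytest
from hypothesis import settings

from renoquant.curves import TimeActivityCurve

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from renoquant.phantom import AcquisitionSchedule, PhantomSpec, aortic_input


@pytest.fixture(scope="session")
def mru_schedule():
    return AcquisitionSchedule.mru_default()


@pytest.fixture(scope="session")
def drs_schedule():
    return AcquisitionSchedule.drs_default()


@pytest.fixture(scope="session")
def mru_aorta(mru_schedule):
    return aortic_input(mru_schedule, **PhantomSpec().aortic_params())


@pytest.fixture
def default_spec():
    return PhantomSpec()


def make_curve(times, values, modality="mru", durations=None, label=None):
    times = np.asarray(times, dtype=float)
    if durations is None:
        durations = np.full(times.shape, float(np.diff(times).min())
                            if len(times) > 1 else 1.0)
    return TimeActivityCurve(times=times, durations=durations,
                             values=np.asarray(values, dtype=float),
                             region_label=label, modality=modality)


def add_noise(curve, sd_fraction, seed):
    """Additive Gaussian noise with sd = sd_fraction x curve peak."""
    rng = np.random.default_rng(seed)
    sd = sd_fraction * curve.values.max()
    return curve.with_values(curve.values
                             + rng.normal(0.0, sd, curve.n_frames))
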