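import numpy as np
import pytest

from qeegvar import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def make_recording(
    samples,
    rate=100.0,
    lab="Lab1",
    subject="m1",
    group="WT",
    dose_events=(),
):
    return Recording(
        lab_id=lab,
        subject_id=subject,
        group=group,
        samples=np.asarray(samples, dtype=float),
        sampling_rate=rate,
        dose_events=list(dose_events),
    )


@pytest.fixture
def noise_recording(rng):
    """10 minutes of unit-variance white noise at 100 Hz."""
    return make_recording(rng.standard_normal(100 * 600))


@pytest.fixture
def sine_recording():
    """Unit 5 Hz sine, 60 s at 100 Hz."""
    t = np.arange(0, 60, 0.01)
    return make_recording(np.sin(2 * np.pi * 5 * t))
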