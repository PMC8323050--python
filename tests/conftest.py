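import numpy as np
import pytest

from diurnal.data import DEFAULT_SCHEDULE, SamplePoint, SubjectProfile


def build_profile(
    values,
    subject_id="S1",
    group="control",
    analyte="cortisol",
    schedule=DEFAULT_SCHEDULE,
):
    """Profile from a value per scheduled slot (None = missing slot row)."""
    elapsed = schedule.elapsed_times()
    assert len(values) == len(elapsed)
    samples = []
    for e, v in zip(elapsed, values):
        day, clock = schedule.day_clock(e)
        samples.append(
            SamplePoint(
                subject_id=subject_id,
                group=group,
                analyte=analyte,
                day=day,
                clock_time=clock,
                elapsed_time=e,
                value=v,
            )
        )
    return SubjectProfile(
        subject_id=subject_id,
        group=group,
        analyte=analyte,
        samples=samples,
        schedule=schedule,
    )


def cosinor_values(mesor, amplitude, acrophase_clock, period=24.0,
                   schedule=DEFAULT_SCHEDULE):
    """Noiseless cosinor curve evaluated at every scheduled slot."""
    t = np.array(schedule.elapsed_times())
    peak_elapsed = (acrophase_clock - schedule.anchor) % 24.0
    return mesor + amplitude * np.cos(2 * np.pi * (t - peak_elapsed) / period)


@pytest.fixture
def noiseless_profile():
    return build_profile(list(cosinor_values(10.0, 5.0, 8.0)))


@pytest.fixture
def noisy_profile():
    rng = np.random.default_rng(42)
    vals = cosinor_values(10.0, 5.0, 8.0) * (1 + rng.normal(0, 0.1, 14))
    return build_profile(list(np.maximum(vals, 0.0)))
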