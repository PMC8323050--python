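"""Synthetic two-day saliva hormone cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes: the
seven-slot two-day sampling design, 24 h cosinor-shaped trajectories per
subject, between-subject variation in mesor, amplitude and (wrapped-normal)
acrophase, multiplicative assay-scale Gaussian noise parameterized by a
coefficient of variation, and sporadic independent missingness.  It does not
model hormone physiology (secretory pulsatility, light response, DLMO
thresholding) — only the shape the downstream cosinor pipeline fits.

Default group structure mirrors the analyzed study groups: cortisol cohorts
of 12 controls / 10 depression / 4 recovery and melatonin cohorts of
12 / 8 / 3.  Control cortisol peaks near 08:00 and control melatonin near
03:50, with the depression group's melatonin peak advanced to near 01:30
(~2.3 h) and its cortisol amplitude damped; the recovery group duplicates
the control distributions.  Noise CVs default to the reported intra-assay
CVs: 6.1 % for cortisol and 10.8 % for melatonin.  Mesor and amplitude
scales are order-of-magnitude typical for saliva assays (cortisol ng/ml,
melatonin pg/ml); the study prints no numeric group means for them, so they
are generator choices, not study estimates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .cosinor import CosinorParams, predict
from .data import DEFAULT_SCHEDULE, SamplePoint, Schedule, SubjectProfile

TRUTH_COLUMNS = (
    "subject_id",
    "group",
    "analyte",
    "mesor",
    "amplitude",
    "acrophase_clock",
    "period",
)


@dataclass(frozen=True)
class SubjectTruth:
    """Generating cosinor parameters for one subject x analyte."""

    subject_id: str
    group: str
    analyte: str
    mesor: float
    amplitude: float
    acrophase_clock: float
    period: float = 24.0


@dataclass(frozen=True)
class GroupSpec:
    """Truth distribution for one group x analyte.

    Acrophase draws are wrapped normal (normal in hours, taken modulo 24);
    mesor and amplitude draws are truncated at zero; ``noise_cv`` is the
    fractional SD of the multiplicative measurement noise and
    ``missing_rate`` the independent per-slot dropout probability.
    """

    label: str
    analyte: str
    n_subjects: int
    mesor_mean: float
    mesor_sd: float
    amplitude_mean: float
    amplitude_sd: float
    acrophase_mean: float
    acrophase_sd: float
    period_mean: float = 24.0
    period_sd: float = 0.0
    noise_cv: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self):
        for name in ("mesor_sd", "amplitude_sd", "acrophase_sd", "period_sd",
                     "noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    """A full cohort recipe; the seed fully determines the output."""

    groups: tuple[GroupSpec, ...]
    schedule: Schedule = DEFAULT_SCHEDULE
    seed: int = 0

    def __post_init__(self):
        keys = [(g.label, g.analyte) for g in self.groups]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (label, analyte) group specs")


# intra-assay CVs of the cortisol and melatonin ELISAs used by the study
ASSAY_CV = {"cortisol": 0.061, "melatonin": 0.108}

_CONTROL_CORTISOL = dict(
    mesor_mean=5.0, mesor_sd=0.6, amplitude_mean=3.5, amplitude_sd=0.5,
    acrophase_mean=8.0, acrophase_sd=1.0,
    noise_cv=ASSAY_CV["cortisol"], missing_rate=0.05,
)
_CONTROL_MELATONIN = dict(
    mesor_mean=12.0, mesor_sd=2.0, amplitude_mean=8.0, amplitude_sd=1.5,
    acrophase_mean=3.833, acrophase_sd=1.0,
    noise_cv=ASSAY_CV["melatonin"], missing_rate=0.05,
)


def default_config(seed: int = 0) -> SimulationConfig:
    """Study-emulating defaults: both analytes, analyzed group sizes."""
    groups = (
        GroupSpec(label="control", analyte="cortisol", n_subjects=12,
                  **_CONTROL_CORTISOL),
        GroupSpec(label="depression", analyte="cortisol", n_subjects=10,
                  **{**_CONTROL_CORTISOL, "amplitude_mean": 2.2,
                     "amplitude_sd": 0.6}),
        GroupSpec(label="recovery", analyte="cortisol", n_subjects=4,
                  **_CONTROL_CORTISOL),
        GroupSpec(label="control", analyte="melatonin", n_subjects=12,
                  **_CONTROL_MELATONIN),
        GroupSpec(label="depression", analyte="melatonin", n_subjects=8,
                  **{**_CONTROL_MELATONIN, "acrophase_mean": 1.5}),
        GroupSpec(label="recovery", analyte="melatonin", n_subjects=3,
                  **_CONTROL_MELATONIN),
    )
    return SimulationConfig(groups=groups, seed=seed)


def make_null_config(base: SimulationConfig) -> SimulationConfig:
    """Give every group of an analyte the first-listed group's distribution.

    Labels and sizes are preserved, so downstream group comparisons run
    unchanged but every between-group difference is null by construction.
    Idempotent.
    """
    reference: dict[str, GroupSpec] = {}
    for g in base.groups:
        reference.setdefault(g.analyte, g)
    groups = tuple(
        dataclasses.replace(
            reference[g.analyte], label=g.label, n_subjects=g.n_subjects
        )
        for g in base.groups
    )
    return dataclasses.replace(base, groups=groups)


def draw_truth(spec: GroupSpec, subject_id: str, rng: np.random.Generator
               ) -> SubjectTruth:
    """Draw one subject's generating parameters from a group distribution.

    Amplitude draws are truncated at 0 and capped at the drawn mesor so every
    true concentration curve is nonnegative (a pure cosinor with A > M would
    dip below zero, which no assay can report).
    """
    mesor = max(0.0, rng.normal(spec.mesor_mean, spec.mesor_sd))
    amplitude = min(
        max(0.0, rng.normal(spec.amplitude_mean, spec.amplitude_sd)), mesor
    )
    acro = rng.normal(spec.acrophase_mean, spec.acrophase_sd) % 24.0
    period = spec.period_mean
    if spec.period_sd > 0:
        period = max(1.0, rng.normal(spec.period_mean, spec.period_sd))
    return SubjectTruth(
        subject_id=subject_id, group=spec.label, analyte=spec.analyte,
        mesor=mesor, amplitude=amplitude, acrophase_clock=acro, period=period,
    )


def truth_params(truth: SubjectTruth) -> CosinorParams:
    """The truth as a CosinorParams, usable with :func:`diurnal.cosinor.predict`."""
    return CosinorParams(
        mesor=truth.mesor,
        amplitude=truth.amplitude,
        acrophase_clock=truth.acrophase_clock,
        period=truth.period,
        r_squared=1.0,
        n_used=0,
    )


def simulate_subject(
    truth: SubjectTruth,
    schedule: Schedule,
    noise_cv: float,
    missing_rate: float,
    rng: np.random.Generator,
) -> SubjectProfile:
    """Noisy two-day profile from one subject's true cosinor curve.

    Each scheduled value is curve(t) * (1 + eps), eps ~ N(0, noise_cv),
    truncated at zero; each slot is independently missing with probability
    ``missing_rate`` (missing slots appear with empty values).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    elapsed = np.array(schedule.elapsed_times())
    curve = predict(truth_params(truth), elapsed, anchor=schedule.anchor)
    noise = rng.normal(0.0, noise_cv, size=elapsed.size) if noise_cv else 0.0
    values = np.maximum(0.0, curve * (1.0 + noise))
    missing = (
        rng.random(elapsed.size) < missing_rate
        if missing_rate
        else np.zeros(elapsed.size, dtype=bool)
    )
    samples = []
    for e, v, m in zip(elapsed, values, missing):
        day, clock = schedule.day_clock(e)
        samples.append(
            SamplePoint(
                subject_id=truth.subject_id,
                group=truth.group,
                analyte=truth.analyte,
                day=day,
                clock_time=clock,
                elapsed_time=float(e),
                value=None if m else float(v),
            )
        )
    return SubjectProfile(
        subject_id=truth.subject_id,
        group=truth.group,
        analyte=truth.analyte,
        samples=samples,
        schedule=schedule,
    )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[SubjectProfile], pd.DataFrame]:
    """Simulate every group of a config; returns (profiles, truth table).

    The truth table holds each subject's generating parameters (columns
    subject_id, group, analyte, mesor, amplitude, acrophase_clock, period)
    so recovery can be scored exactly.  Deterministic in ``config.seed``.
    """
    # independent child streams so the drawn truths are invariant to the
    # noise and missingness settings (same seed -> same subjects)
    truth_seed, noise_seed = np.random.SeedSequence(config.seed).spawn(2)
    rng_truth = np.random.default_rng(truth_seed)
    rng_noise = np.random.default_rng(noise_seed)
    profiles: list[SubjectProfile] = []
    truth_rows = []
    for spec in config.groups:
        for i in range(spec.n_subjects):
            sid = f"{spec.label[:3].upper()}{i + 1:02d}"
            truth = draw_truth(spec, sid, rng_truth)
            truth_rows.append(dataclasses.asdict(truth))
            profiles.append(
                simulate_subject(
                    truth, config.schedule, spec.noise_cv, spec.missing_rate,
                    rng_noise,
                )
            )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return profiles, truth


# ---------------------------------------------------------------------------
# YAML config round-trip

def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "seed": config.seed,
        "schedule": {
            "clock_times": list(config.schedule.clock_times),
            "n_days": config.schedule.n_days,
        },
        "groups": [dataclasses.asdict(g) for g in config.groups],
    }


def config_from_dict(d: dict) -> SimulationConfig:
    sched = d.get("schedule", {})
    schedule = Schedule(
        clock_times=tuple(sched.get("clock_times", DEFAULT_SCHEDULE.clock_times)),
        n_days=int(sched.get("n_days", DEFAULT_SCHEDULE.n_days)),
    )
    groups = tuple(GroupSpec(**g) for g in d["groups"])
    return SimulationConfig(groups=groups, schedule=schedule,
                            seed=int(d.get("seed", 0)))


def load_config(path: str | Path) -> SimulationConfig:
    with open(path, encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(config: SimulationConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
    return path
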