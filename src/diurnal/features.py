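"""Per-subject rhythm feature ledger for two-day hormone profiles.

Twelve features per subject x analyte, mirroring the panel-by-panel analysis
of the study's parameter figures:

a. period            — wavelength of the bounded free-period cosinor fit (h)
b. acrophase_clock   — clock time of the fixed-24 h fitted curve maximum
c. fitted_peak       — mesor + amplitude of the fixed-24 h fit
d. fitted_mesor      — mesor of the fixed-24 h fit
e. avg_24h           — mean of all present measurements over both days
f. max_level         — measured value at the analyte's anchored maximum slot
                       (cortisol: day-2 08:00; melatonin: day-2 05:00)
g. range             — empirical max minus min over all present samples
h. two_day_diff      — mean |day1 - day2| over clock times present both days
i. slope_day1        — OLS slope over 08:00, 11:00, 14:00 of day 1
j. slope_day2        — same for day 2
k. slope_night1      — OLS slope over the analyte's night triplet, night 1
                       (cortisol: 01:00, 05:00 and the next 08:00; melatonin:
                       22:00, 01:00, 05:00)
l. slope_night2      — same triplet one day later

All slopes are computed against elapsed time, never raw clock numerals: the
night samples cross midnight, so the cortisol night triplet spans elapsed
{17, 21, 24} hours (night 1) — the raw clock values (1, 5, 8) happen to give
the same spacing, but only because the elapsed axis makes them monotone.
Under the standard 14-slot schedule the cortisol night-2 triplet has no
sampled third point (the day-3 08:00 was never collected), so that slope is
a two-point slope and carries the ``slope_night2_degraded`` flag.

``max_level`` is the anchored-slot measurement, not the per-subject empirical
maximum; the empirical extremes enter only through ``range``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cosinor import CosinorParams
from .data import SubjectProfile

FEATURE_NAMES = (
    "period",
    "acrophase_clock",
    "fitted_peak",
    "fitted_mesor",
    "avg_24h",
    "max_level",
    "range",
    "two_day_diff",
    "slope_day1",
    "slope_day2",
    "slope_night1",
    "slope_night2",
)

#: clock time of the anchored-maximum slot, on day 2
ANCHOR_MAX_CLOCK = {"cortisol": 8.0, "melatonin": 5.0}

#: night-slope triplets as clock times tagged with a day offset relative to
#: the sampling day (0 = same sampling day's night block, +1 = next day)
NIGHT_TRIPLETS = {
    "cortisol": ((1.0, 0), (5.0, 0), (8.0, 1)),
    "melatonin": ((22.0, 0), (1.0, 0), (5.0, 0)),
}
DAY_TRIPLET = (8.0, 11.0, 14.0)


@dataclass
class FeatureSet:
    """The 12-feature ledger for one subject x analyte; None = not derivable."""

    subject_id: str
    group: str
    analyte: str
    period: float | None = None
    acrophase_clock: float | None = None
    fitted_peak: float | None = None
    fitted_mesor: float | None = None
    avg_24h: float | None = None
    max_level: float | None = None
    range: float | None = None
    two_day_diff: float | None = None
    slope_day1: float | None = None
    slope_day2: float | None = None
    slope_night1: float | None = None
    slope_night2: float | None = None
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _slope(elapsed: list[float], values: list[float]) -> float | None:
    """OLS slope of value against elapsed hours; None below 2 points."""
    if len(values) < 2:
        return None
    return float(np.polyfit(elapsed, values, 1)[0])


def _triplet_points(
    profile: SubjectProfile, clocks_with_offsets, base_day: int
) -> tuple[list[float], list[float]]:
    sched = profile.schedule
    elapsed, values = [], []
    for clock, offset in clocks_with_offsets:
        e = sched.elapsed(base_day + offset, clock)
        v = profile.value_at(e)
        if v is not None:
            elapsed.append(e)
            values.append(v)
    return elapsed, values


def extract_features(
    profile: SubjectProfile,
    cosinor_fixed: CosinorParams,
    cosinor_free: CosinorParams | None = None,
    two_day_diff_stat: str = "mean",
) -> FeatureSet:
    """Compute the 12-feature ledger for one profile.

    ``cosinor_fixed`` supplies acrophase, peak and mesor; ``cosinor_free``
    supplies the period feature (missing when absent).  ``two_day_diff_stat``
    selects the replicability statistic: ``"mean"`` (mean absolute difference
    between matched time points, the default) or ``"sum"`` (their
    accumulation).
    """
    if two_day_diff_stat not in ("mean", "sum"):
        raise ValueError(f"unknown two_day_diff_stat {two_day_diff_stat!r}")
    sched = profile.schedule
    flags: list[str] = []
    fs = FeatureSet(profile.subject_id, profile.group, profile.analyte)

    fs.period = None if cosinor_free is None else cosinor_free.period
    if cosinor_free is not None and "period_at_bound" in cosinor_free.flags:
        flags.append("period_at_bound")
    if "acrophase_undefined" in cosinor_fixed.flags:
        flags.append("acrophase_undefined")
    else:
        fs.acrophase_clock = cosinor_fixed.acrophase_clock
    fs.fitted_peak = cosinor_fixed.mesor + cosinor_fixed.amplitude
    fs.fitted_mesor = cosinor_fixed.mesor

    values = [s.value for s in profile.present]
    if values:
        fs.avg_24h = float(np.mean(values))
        fs.range = float(max(values) - min(values))

    anchor_clock = ANCHOR_MAX_CLOCK[profile.analyte]
    fs.max_level = profile.value_at(sched.elapsed(2, anchor_clock))
    if fs.max_level is None:
        flags.append("max_level_missing")

    # matched-clock-time day-1 vs day-2 differences
    diffs = []
    for clock in sched.clock_times:
        v1 = profile.value_at(sched.elapsed(1, clock))
        v2 = profile.value_at(sched.elapsed(2, clock))
        if v1 is not None and v2 is not None:
            diffs.append(abs(v1 - v2))
    if diffs:
        fs.two_day_diff = float(
            np.mean(diffs) if two_day_diff_stat == "mean" else np.sum(diffs)
        )
    else:
        flags.append("two_day_diff_missing")

    day_trip = [(c, 0) for c in DAY_TRIPLET]
    night_trip = NIGHT_TRIPLETS[profile.analyte]
    for name, trip in (
        ("slope_day1", day_trip),
        ("slope_day2", day_trip),
        ("slope_night1", night_trip),
        ("slope_night2", night_trip),
    ):
        base_day = 1 if name.endswith("1") else 2
        elapsed, vals = _triplet_points(profile, trip, base_day)
        slope = _slope(elapsed, vals)
        setattr(fs, name, slope)
        if slope is None:
            flags.append(f"{name}_missing")
        elif len(vals) == 2:
            flags.append(f"{name}_degraded")

    fs.flags = tuple(flags)
    return fs


def feature_table(
    profiles: Iterable[SubjectProfile],
    fits: Mapping[tuple[str, str], tuple[CosinorParams, CosinorParams | None]],
    two_day_diff_stat: str = "mean",
) -> pd.DataFrame:
    """One ledger row per subject x analyte, columns in panel order a-l.

    ``fits`` maps (subject_id, analyte) to (fixed-24 fit, free-period fit or
    None).  A fit keyed to a subject absent from ``profiles`` is a
    consistency error.
    """
    profiles = list(profiles)
    keys = {(p.subject_id, p.analyte) for p in profiles}
    orphans = set(fits) - keys
    if orphans:
        raise ValueError(f"fits for subjects not in profiles: {sorted(orphans)}")
    rows = []
    for p in profiles:
        fixed, free = fits[(p.subject_id, p.analyte)]
        fs = extract_features(p, fixed, free, two_day_diff_stat=two_day_diff_stat)
        row = fs.as_dict()
        row["flags"] = ";".join(fs.flags)
        rows.append(row)
    cols = ["subject_id", "group", "analyte", *FEATURE_NAMES, "flags"]
    return pd.DataFrame(rows, columns=cols).astype(
        {name: float for name in FEATURE_NAMES}
    )
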