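"""Domain types and CSV I/O for timed two-day saliva hormone profiles.

The study design samples saliva at seven clock times — 08:00, 11:00, 14:00,
19:00, 22:00, 01:00 and 05:00 — on two consecutive days (14 scheduled slots
per subject and analyte).  Concentrations are cortisol in ng/ml and melatonin
in pg/ml.

Timeline convention
-------------------
Internally time is continuous *elapsed hours* since the first scheduled
sample (day-1 08:00 = 0).  The two night samples (01:00, 05:00) belong to the
sampling day whose evening precedes them, so they fall on the next calendar
day: elapsed = (clock - 8) mod 24 + 24*(day - 1), giving
{0, 3, 6, 11, 14, 17, 21} for day 1 and the same + 24 for day 2.  The study
timestamps night samples only by sampling day, so this convention is an
inference from the two-consecutive-day design; it is the only monotone axis
on which slopes and cosinor fits are well defined.  Clock time is recovered
as (8 + elapsed) mod 24.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

GROUPS = ("control", "depression", "recovery", "mania")
ANALYTES = ("cortisol", "melatonin")
UNITS = {"cortisol": "ng/ml", "melatonin": "pg/ml"}

CSV_COLUMNS = ("subject_id", "group", "analyte", "day", "clock_time", "value")


class ProfileValidationError(ValueError):
    """Raised when rows of a profile table violate the schedule or domain rules.

    Carries a list of per-row messages (with 1-based data row numbers where
    applicable) in ``errors``.
    """

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass(frozen=True)
class Schedule:
    """A within-day sampling schedule repeated over consecutive days.

    ``clock_times`` are listed in sampling order starting at the anchor
    (first) sample; times earlier than the anchor are taken on the following
    calendar day.
    """

    clock_times: tuple[float, ...] = (8.0, 11.0, 14.0, 19.0, 22.0, 1.0, 5.0)
    n_days: int = 2

    @property
    def anchor(self) -> float:
        return self.clock_times[0]

    @property
    def n_slots(self) -> int:
        return len(self.clock_times) * self.n_days

    def elapsed(self, day: int, clock_time: float) -> float:
        """Elapsed hours since day-1 anchor for a (day, clock) slot."""
        return (clock_time - self.anchor) % 24.0 + 24.0 * (day - 1)

    def day_clock(self, elapsed: float) -> tuple[int, float]:
        """Inverse of :meth:`elapsed` on scheduled slots."""
        day = int(math.floor(elapsed / 24.0)) + 1
        return day, (self.anchor + elapsed) % 24.0

    def elapsed_times(self) -> list[float]:
        """All scheduled elapsed times, strictly increasing."""
        return [
            self.elapsed(day, ct)
            for day in range(1, self.n_days + 1)
            for ct in self.clock_times
        ]

    def contains(self, clock_time: float, tol: float = 1e-9) -> bool:
        return any(abs(clock_time - ct) <= tol for ct in self.clock_times)


DEFAULT_SCHEDULE = Schedule()


@dataclass(frozen=True)
class SamplePoint:
    """One timed hormone measurement; ``value`` is None for a missing slot."""

    subject_id: str
    group: str
    analyte: str
    day: int
    clock_time: float
    elapsed_time: float
    value: float | None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ProfileValidationError([f"unknown group label {self.group!r}"])
        if self.analyte not in ANALYTES:
            raise ProfileValidationError([f"unknown analyte {self.analyte!r}"])
        if not 0 <= self.clock_time < 24:
            raise ProfileValidationError(
                [f"clock_time {self.clock_time} outside [0, 24)"]
            )
        if self.value is not None and self.value < 0:
            raise ProfileValidationError(
                [f"negative concentration {self.value} for {self.subject_id}"]
            )


@dataclass
class SubjectProfile:
    """One subject's ordered two-day series for one analyte.

    ``samples`` holds one entry per scheduled slot that appears in the data,
    sorted by elapsed time; explicitly-missing slots carry ``value=None``.
    ``n_missing`` counts scheduled slots without a value, whether the slot is
    absent from the table or present with an empty cell.
    """

    subject_id: str
    group: str
    analyte: str
    samples: list[SamplePoint] = field(default_factory=list)
    schedule: Schedule = DEFAULT_SCHEDULE

    def __post_init__(self):
        self.samples = sorted(self.samples, key=lambda s: s.elapsed_time)
        elapsed = [s.elapsed_time for s in self.samples]
        if len(set(elapsed)) != len(elapsed):
            raise ProfileValidationError(
                [f"duplicate elapsed times for {self.subject_id}/{self.analyte}"]
            )

    @property
    def present(self) -> list[SamplePoint]:
        return [s for s in self.samples if s.value is not None]

    @property
    def n_missing(self) -> int:
        return self.schedule.n_slots - len(self.present)

    def value_at(self, elapsed_time: float, tol: float = 1e-9) -> float | None:
        """Measured value at a scheduled elapsed time, or None if missing."""
        for s in self.samples:
            if abs(s.elapsed_time - elapsed_time) <= tol:
                return s.value
        return None

    def times_values(self):
        """(elapsed, value) arrays over present samples."""
        pres = self.present
        return (
            [s.elapsed_time for s in pres],
            [s.value for s in pres],
        )


def _parse_row(
    row: dict, rownum: int, schedule: Schedule, permissive: bool
) -> SamplePoint | str:
    """Turn one CSV row into a SamplePoint, or an error message string."""
    try:
        subject_id = row["subject_id"].strip()
        group = row["group"].strip().lower()
        analyte = row["analyte"].strip().lower()
        day = int(row["day"])
        clock_time = float(row["clock_time"])
        raw = (row["value"] or "").strip()
        value = float(raw) if raw else None
    except (KeyError, TypeError, ValueError) as exc:
        return f"row {rownum}: malformed row ({exc})"
    if group not in GROUPS:
        return f"row {rownum}: unknown group label {group!r}"
    if analyte not in ANALYTES:
        return f"row {rownum}: unknown analyte {analyte!r}"
    if day not in range(1, schedule.n_days + 1):
        return f"row {rownum}: day {day} outside 1..{schedule.n_days}"
    if not 0 <= clock_time < 24:
        return f"row {rownum}: clock_time {clock_time} outside [0, 24)"
    if not permissive and not schedule.contains(clock_time):
        return (
            f"row {rownum}: clock_time {clock_time} not in schedule "
            f"{schedule.clock_times}"
        )
    if value is not None and value < 0:
        return f"row {rownum}: negative value {value}"
    return SamplePoint(
        subject_id=subject_id,
        group=group,
        analyte=analyte,
        day=day,
        clock_time=clock_time,
        elapsed_time=schedule.elapsed(day, clock_time),
        value=value,
    )


def read_profiles(
    path: str | Path,
    schedule: Schedule = DEFAULT_SCHEDULE,
    permissive: bool = False,
) -> list[SubjectProfile]:
    """Read a long-format CSV of timed measurements into validated profiles.

    Columns: subject_id, group, analyte, day, clock_time, value (empty cell =
    missing).  Rows are grouped by subject x analyte; elapsed time is derived
    from (day, clock_time).  Off-schedule clock times are rejected unless
    ``permissive``.  All row-level problems are collected and raised together
    as :class:`ProfileValidationError` naming the offending data rows.
    """
    path = Path(path)
    errors: list[str] = []
    points: dict[tuple[str, str], list[SamplePoint]] = {}
    seen: set[tuple[str, str, int, float]] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(CSV_COLUMNS) <= set(
            reader.fieldnames
        ):
            raise ProfileValidationError(
                [f"line 1: expected header columns {CSV_COLUMNS}, "
                 f"got {reader.fieldnames}"]
            )
        for rownum, row in enumerate(reader, start=1):
            parsed = _parse_row(row, rownum, schedule, permissive)
            if isinstance(parsed, str):
                errors.append(parsed)
                continue
            key = (parsed.subject_id, parsed.analyte, parsed.day, parsed.clock_time)
            if key in seen:
                errors.append(
                    f"row {rownum}: duplicate sample {key}"
                )
                continue
            seen.add(key)
            points.setdefault((parsed.subject_id, parsed.analyte), []).append(parsed)
    if errors:
        raise ProfileValidationError(errors)
    profiles = []
    for (subject_id, analyte), pts in points.items():
        profiles.append(
            SubjectProfile(
                subject_id=subject_id,
                group=pts[0].group,
                analyte=analyte,
                samples=pts,
                schedule=schedule,
            )
        )
    profiles.sort(key=lambda p: (p.subject_id, p.analyte))
    return profiles


def write_profiles(profiles: Iterable[SubjectProfile], path: str | Path) -> Path:
    """Write profiles to the long-format CSV dialect read by read_profiles.

    Missing values are written as empty cells, never zeros; clock times are
    decimal hours.  read_profiles(write_profiles(p)) round-trips.
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for prof in profiles:
            for s in prof.samples:
                writer.writerow(
                    [
                        prof.subject_id,
                        prof.group,
                        prof.analyte,
                        s.day,
                        _fmt_clock(s.clock_time),
                        "" if s.value is None else repr(s.value),
                    ]
                )
    return path


def _fmt_clock(ct: float) -> str:
    return str(int(ct)) if float(ct).is_integer() else repr(ct)


def profiles_equal(a: SubjectProfile, b: SubjectProfile) -> bool:
    """Structural equality used by round-trip checks."""
    if (a.subject_id, a.group, a.analyte) != (b.subject_id, b.group, b.analyte):
        return False
    if len(a.samples) != len(b.samples):
        return False
    for sa, sb in zip(a.samples, b.samples):
        if (sa.day, sa.clock_time) != (sb.day, sb.clock_time):
            return False
        if (sa.value is None) != (sb.value is None):
            return False
        if sa.value is not None and sa.value != sb.value:
            return False
    return True
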