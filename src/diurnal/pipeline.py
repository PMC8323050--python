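"""End-to-end analysis: exclusion, cosinor fits, features, comparisons.

This is the library form of the command-line ``analyze`` stage: apply the
missing-data exclusion rule, fit every retained profile with the fixed-24 h
cosinor (closed form) and the bounded free-period variant, assemble the
12-feature ledger, run the between-group comparisons, and summarize each
group's acrophase distribution as a mean vector with a Rayleigh uniformity
check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import circular, compare, cosinor, features
from .compare import DEFAULT_EXCLUSION_THRESHOLD, DEFAULT_PAIRINGS
from .cosinor import CosinorParams, InsufficientDataError
from .data import SubjectProfile

FIT_COLUMNS = (
    "subject_id", "group", "analyte", "form", "period_mode", "mesor",
    "amplitude", "acrophase_clock", "period", "r_squared", "n_used", "flags",
)


@dataclass
class AnalysisResult:
    """All tables produced by one pipeline run."""

    fits: pd.DataFrame
    feature_table: pd.DataFrame
    comparisons: pd.DataFrame
    circular_summary: pd.DataFrame
    exclusions: pd.DataFrame
    group_summary: pd.DataFrame
    warnings: list[str] = field(default_factory=list)
    retained_profiles: list[SubjectProfile] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return len(self.retained_profiles)


def _fit_row(profile: SubjectProfile, params: CosinorParams, period_mode: str
             ) -> dict:
    return {
        "subject_id": profile.subject_id,
        "group": profile.group,
        "analyte": profile.analyte,
        "form": params.form,
        "period_mode": period_mode,
        "mesor": params.mesor,
        "amplitude": params.amplitude,
        "acrophase_clock": params.acrophase_clock,
        "period": params.period,
        "r_squared": params.r_squared,
        "n_used": params.n_used,
        "flags": ";".join(sorted(params.flags)),
    }


def fit_profiles(
    profiles: list[SubjectProfile],
    free_period: bool = True,
) -> tuple[dict, pd.DataFrame, list[str]]:
    """Fixed-24 (and optionally free-period) fits for every profile.

    Returns (fits dict keyed (subject_id, analyte) -> (fixed, free-or-None),
    long-format fit table, warnings).
    """
    fits: dict = {}
    rows, warnings = [], []
    for p in profiles:
        model = cosinor.Cosinor.from_profile(p)
        try:
            fixed = model.fit().params
        except InsufficientDataError as exc:
            warnings.append(f"{p.subject_id}/{p.analyte}: {exc}")
            continue
        free = None
        if free_period:
            try:
                free = model.fit_nonlinear("free_bounded").params
            except InsufficientDataError as exc:
                warnings.append(
                    f"{p.subject_id}/{p.analyte}: free period skipped ({exc})"
                )
        fits[(p.subject_id, p.analyte)] = (fixed, free)
        rows.append(_fit_row(p, fixed, "fixed24"))
        if free is not None:
            rows.append(_fit_row(p, free, "free_bounded"))
        for params in (fixed,) + ((free,) if free is not None else ()):
            if params.flags:
                warnings.append(
                    f"{p.subject_id}/{p.analyte}: {';'.join(sorted(params.flags))}"
                )
    return fits, pd.DataFrame(rows, columns=FIT_COLUMNS), warnings


def circular_group_summary(feature_table: pd.DataFrame) -> pd.DataFrame:
    """Mean acrophase vector and Rayleigh test per group x analyte."""
    rows = []
    for (analyte, group), sub in feature_table.groupby(["analyte", "group"]):
        acro = sub["acrophase_clock"].dropna().to_numpy() % 24.0
        row = {
            "analyte": analyte,
            "group": group,
            "n": int(acro.size),
            "mean_clock": math.nan,
            "resultant_length": math.nan,
            "rayleigh_z": math.nan,
            "rayleigh_p": math.nan,
        }
        if acro.size:
            summ = circular.mean_vector(circular.phase_angle(acro))
            row["mean_clock"] = summ.mean_clock
            row["resultant_length"] = summ.resultant_length
            if acro.size >= 3:
                z, p = circular.rayleigh_test(circular.phase_angle(acro))
                row["rayleigh_z"], row["rayleigh_p"] = z, p
        rows.append(row)
    return pd.DataFrame(rows)


def analyze(
    profiles: list[SubjectProfile],
    exclusion_threshold: int = DEFAULT_EXCLUSION_THRESHOLD,
    pairings=DEFAULT_PAIRINGS,
    t_variant: str = "pooled",
    fdr: bool = False,
    free_period: bool = True,
    two_day_diff_stat: str = "mean",
) -> AnalysisResult:
    """Run the full per-subject -> feature -> group-comparison pipeline."""
    retained, excluded = compare.apply_exclusion(profiles, exclusion_threshold)
    if not retained:
        raise InsufficientDataError(
            f"no retained profiles ({len(excluded)} excluded at threshold "
            f"{exclusion_threshold})"
        )
    fits, fit_table, warnings = fit_profiles(retained, free_period=free_period)
    fitted = [p for p in retained if (p.subject_id, p.analyte) in fits]
    table = features.feature_table(
        fitted, fits, two_day_diff_stat=two_day_diff_stat
    )
    comparisons = compare.compare_all(
        table, pairings=pairings, variant=t_variant, fdr=fdr
    )
    exclusion_rows = [
        {
            "subject_id": e.profile.subject_id,
            "analyte": e.profile.analyte,
            "group": e.profile.group,
            "n_missing": e.n_missing,
            "reason": e.reason,
        }
        for e in excluded
    ]
    return AnalysisResult(
        fits=fit_table,
        feature_table=table,
        comparisons=comparisons,
        circular_summary=circular_group_summary(table),
        exclusions=pd.DataFrame(
            exclusion_rows,
            columns=["subject_id", "analyte", "group", "n_missing", "reason"],
        ),
        group_summary=compare.group_feature_summary(table),
        warnings=warnings,
        retained_profiles=fitted,
    )


def acrophase_group_difference(
    feature_table: pd.DataFrame, analyte: str, group_a: str, group_b: str
) -> float:
    """Circular difference (hours, in [-12, 12)) of group mean acrophases.

    Positive means group_b peaks earlier than group_a (a phase advance of
    group_b relative to group_a).
    """
    sub = feature_table[feature_table["analyte"] == analyte]
    means = {}
    for g in (group_a, group_b):
        acro = sub[sub["group"] == g]["acrophase_clock"].dropna().to_numpy()
        if acro.size == 0:
            return math.nan
        means[g] = circular.mean_vector(circular.phase_angle(acro % 24.0)).mean_clock
    diff = (means[group_a] - means[group_b] + 12.0) % 24.0 - 12.0
    return float(diff)
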