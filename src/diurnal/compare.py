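"""Exclusion rule, Student's t tests, and assembly of group-comparison tables.

A subject x analyte profile is dropped when it has missing values at more
than ``threshold`` (default 4) of its 14 scheduled time points; exclusion is
applied per analyte, so a subject can be retained for cortisol and excluded
for melatonin.  Every retained feature is compared between group pairs with
a two-sided Student's t test (pooled variance by default, Welch by flag) at
alpha = .05, with no multiple-testing correction by default — matching the
source analysis of 12 features per hormone at raw alpha; Benjamini-Hochberg
adjustment is available behind ``fdr=True`` and should be preferred when the
goal is confirmatory inference rather than replication of the original
procedure.  The acrophase feature is additionally routed to the
Watson-Williams test, since peak times are circular; both p values are
reported side by side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .circular import DegenerateDispersionError, phase_angle, watson_williams
from .data import SubjectProfile
from .features import FEATURE_NAMES

ALPHA = 0.05
DEFAULT_EXCLUSION_THRESHOLD = 4
DEFAULT_PAIRINGS = (("control", "depression"), ("control", "recovery"))


class DegenerateVarianceError(ValueError):
    """Zero variance in both samples with unequal means; t is unbounded."""


@dataclass(frozen=True)
class Exclusion:
    profile: SubjectProfile
    n_missing: int
    reason: str


def apply_exclusion(
    profiles: Iterable[SubjectProfile],
    threshold: int = DEFAULT_EXCLUSION_THRESHOLD,
) -> tuple[list[SubjectProfile], list[Exclusion]]:
    """Split profiles into retained and excluded-with-reason.

    A profile is excluded iff its missing-slot count strictly exceeds
    ``threshold`` (the ">4 time points" rule at the default).
    """
    retained, excluded = [], []
    for p in profiles:
        if p.n_missing > threshold:
            excluded.append(
                Exclusion(
                    profile=p,
                    n_missing=p.n_missing,
                    reason=(
                        f"{p.n_missing} missing time points "
                        f"(> {threshold} allowed)"
                    ),
                )
            )
        else:
            retained.append(p)
    return retained, excluded


def students_t(
    values_a, values_b, variant: str = "pooled"
) -> tuple[float, float, float]:
    """Two-sided Student's t test; returns (t, df, p).

    ``variant`` is ``"pooled"`` (classical equal-variance test) or
    ``"welch"``.  Zero variance in both groups with equal means gives
    (0, df, 1); with unequal means it raises
    :class:`DegenerateVarianceError`.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        raise DegenerateVarianceError(
            "zero variance in both samples with unequal means"
        )
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def group_mean_sem(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(values))
    sem = float(stats.sem(values)) if values.size > 1 else math.nan
    return mean, sem


def compare_all(
    feature_table: pd.DataFrame,
    pairings: Sequence[tuple[str, str]] = DEFAULT_PAIRINGS,
    variant: str = "pooled",
    fdr: bool = False,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """One comparison row per feature x analyte x group pairing.

    Missing feature values are dropped listwise per comparison; a side with
    fewer than two usable values yields a row marked not computable (this is
    how a single-subject group, like the study's one manic-episode patient,
    flows through without a test).  The ``acrophase_clock`` rows also carry
    Watson-Williams F and p.  With ``fdr`` the t-test p values are
    Benjamini-Hochberg adjusted within each analyte x pairing family and
    significance is called on the adjusted values.
    """
    rows = []
    analytes = sorted(feature_table["analyte"].unique())
    for analyte in analytes:
        sub = feature_table[feature_table["analyte"] == analyte]
        for group_a, group_b in pairings:
            va_all = sub[sub["group"] == group_a]
            vb_all = sub[sub["group"] == group_b]
            for feat in FEATURE_NAMES:
                a = va_all[feat].dropna().to_numpy()
                b = vb_all[feat].dropna().to_numpy()
                row = {
                    "feature": feat,
                    "analyte": analyte,
                    "group_a": group_a,
                    "group_b": group_b,
                    "n_a": int(a.size),
                    "n_b": int(b.size),
                    "mean_a": math.nan,
                    "sem_a": math.nan,
                    "mean_b": math.nan,
                    "sem_b": math.nan,
                    "t_statistic": math.nan,
                    "df": math.nan,
                    "p_value": math.nan,
                    "significant": False,
                    "computable": True,
                    "note": "",
                    "ww_F": math.nan,
                    "ww_p": math.nan,
                }
                if a.size:
                    row["mean_a"], row["sem_a"] = group_mean_sem(a)
                if b.size:
                    row["mean_b"], row["sem_b"] = group_mean_sem(b)
                if a.size < 2 or b.size < 2:
                    row["computable"] = False
                    row["note"] = "not computable: fewer than 2 values in a group"
                else:
                    try:
                        t, df, p = students_t(a, b, variant=variant)
                        row.update(t_statistic=t, df=df, p_value=p)
                    except DegenerateVarianceError:
                        row["computable"] = False
                        row["note"] = "not computable: degenerate variance"
                    if feat == "acrophase_clock" and row["computable"]:
                        try:
                            ww = watson_williams(
                                [phase_angle(a % 24.0), phase_angle(b % 24.0)]
                            )
                            row["ww_F"] = ww.F_statistic
                            row["ww_p"] = ww.p_value
                            if ww.assumption_warning:
                                row["note"] = "watson-williams kappa < 2"
                        except (DegenerateDispersionError, ValueError) as exc:
                            row["note"] = f"watson-williams failed: {exc}"
                rows.append(row)
    out = pd.DataFrame(rows)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        out["p_adjusted"] = math.nan
        for _, idx in out.groupby(["analyte", "group_a", "group_b"]).groups.items():
            mask = out.loc[idx, "p_value"].notna()
            sel = out.loc[idx][mask].index
            if len(sel):
                out.loc[sel, "p_adjusted"] = multipletests(
                    out.loc[sel, "p_value"], method="fdr_bh"
                )[1]
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["significant"] = out["p_value"] < alpha
    return out


def group_feature_summary(feature_table: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean, SEM and n of every feature (long format)."""
    rows = []
    for (analyte, group), sub in feature_table.groupby(["analyte", "group"]):
        for feat in FEATURE_NAMES:
            vals = sub[feat].dropna().to_numpy()
            mean, sem = group_mean_sem(vals) if vals.size else (math.nan, math.nan)
            rows.append(
                {
                    "analyte": analyte,
                    "group": group,
                    "feature": feat,
                    "n": int(vals.size),
                    "mean": mean,
                    "sem": sem,
                }
            )
    return pd.DataFrame(rows)
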