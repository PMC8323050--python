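"""Circular statistics for acrophase clock times.

Peak clock times live on a 24 h circle; they are mapped to angles by
theta = 2*pi*t/24 with midnight at angle 0.  The module provides the mean
resultant vector (direction = average peak time, length = phase agreement),
the Rayleigh uniformity test, and the Watson-Williams F test for equality of
mean directions between groups — the circular analogue of one-way ANOVA.

Watson-Williams statistic (Mardia & Jupp; Zar): with per-group resultant
lengths R_i (unnormalized), pooled resultant R and N angles in k groups,

    F = K * (N - k) * (sum R_i - R) / ((k - 1) * (N - sum R_i))

where K = 1 + 3/(8*kappa) corrects for the von Mises concentration kappa,
estimated from the within-group mean resultant length rbar = sum R_i / N by
the standard maximum-likelihood approximation.  The test assumes roughly
von Mises samples with common, reasonably high concentration; a warning flag
is set when kappa_hat < 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

HOURS_PER_CYCLE = 24.0
#: below this concentration the Watson-Williams approximation is unreliable
KAPPA_WARN_THRESHOLD = 2.0
#: mean resultant length below which the mean direction is undefined
RESULTANT_UNDEFINED_TOL = 1e-12

# regime boundaries of the ML kappa approximation (Fisher 1993, eq. 4.40-4.42)
_KAPPA_REGIME_1 = 0.53
_KAPPA_REGIME_2 = 0.85


class DegenerateDispersionError(ValueError):
    """Zero within-group angular dispersion; the F statistic is unbounded."""


@dataclass(frozen=True)
class CircularSummary:
    """Mean vector of a set of phase angles.

    ``mean_angle`` is NaN (flagged) when the resultant length is numerically
    zero — antipodal cancellation leaves no defined direction.
    """

    n: int
    mean_angle: float
    resultant_length: float
    mean_clock: float
    weights_used: bool = False

    @property
    def mean_direction_defined(self) -> bool:
        return not math.isnan(self.mean_angle)


@dataclass(frozen=True)
class WatsonWilliamsResult:
    F_statistic: float
    df_between: int
    df_within: int
    p_value: float
    kappa_hat: float
    assumption_warning: bool


def phase_angle(clock_time) -> np.ndarray | float:
    """Map clock hours in [0, 24) to radians in [0, 2*pi), midnight at 0."""
    ct = np.asarray(clock_time, dtype=float)
    if np.any(ct < 0) or np.any(ct >= HOURS_PER_CYCLE):
        raise ValueError("clock_time must lie in [0, 24)")
    out = 2.0 * np.pi * ct / HOURS_PER_CYCLE
    return float(out) if out.ndim == 0 else out


def clock_from_angle(angle) -> np.ndarray | float:
    """Inverse of :func:`phase_angle`, wrapped to [0, 24)."""
    a = np.asarray(angle, dtype=float)
    out = (a * HOURS_PER_CYCLE / (2.0 * np.pi)) % HOURS_PER_CYCLE
    return float(out) if out.ndim == 0 else out


def mean_vector(angles, weights=None) -> CircularSummary:
    """Mean resultant vector of phase angles, optionally weighted.

    The rectangular means of (cos, sin) give the vector; its direction is the
    mean angle (average peak time on the clock face) and its norm the
    resultant length in [0, 1] (1 = perfect agreement).
    """
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("mean_vector needs at least one angle")
    if weights is None:
        w = np.ones_like(a)
        weights_used = False
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != a.shape:
            raise ValueError("weights must match angles in length")
        if np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative, not all zero")
        weights_used = True
    c = float(np.sum(w * np.cos(a)) / w.sum())
    s = float(np.sum(w * np.sin(a)) / w.sum())
    r = math.hypot(c, s)
    if r < RESULTANT_UNDEFINED_TOL:
        mean_angle = math.nan
        mean_clock = math.nan
    else:
        mean_angle = math.atan2(s, c) % (2.0 * np.pi)
        mean_clock = mean_angle * HOURS_PER_CYCLE / (2.0 * np.pi)
    return CircularSummary(
        n=int(a.size),
        mean_angle=mean_angle,
        resultant_length=min(r, 1.0),
        mean_clock=mean_clock,
        weights_used=weights_used,
    )


def kappa_ml(rbar: float) -> float:
    """ML approximation of the von Mises concentration from mean resultant length."""
    if not 0.0 <= rbar <= 1.0:
        raise ValueError("mean resultant length must lie in [0, 1]")
    if rbar < _KAPPA_REGIME_1:
        return 2.0 * rbar + rbar**3 + 5.0 * rbar**5 / 6.0
    if rbar < _KAPPA_REGIME_2:
        return -0.4 + 1.39 * rbar + 0.43 / (1.0 - rbar)
    denom = rbar**3 - 4.0 * rbar**2 + 3.0 * rbar
    if denom <= 0.0:
        return math.inf
    return 1.0 / denom


def watson_williams(groups) -> WatsonWilliamsResult:
    """Watson-Williams F test for equality of group mean directions.

    ``groups`` is a sequence of angle arrays (radians), one per group, each
    with n >= 2.  Raises :class:`DegenerateDispersionError` when the
    within-group dispersion is numerically zero (every group perfectly
    concentrated), where the F statistic is unbounded.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    for g in gs:
        if g.size < 2:
            raise ValueError("each group needs at least two angles")
        if not np.all(np.isfinite(g)):
            raise ValueError("angles must be finite")
    k = len(gs)
    N = sum(g.size for g in gs)
    R_i = [g.size * mean_vector(g).resultant_length for g in gs]
    allangles = np.concatenate(gs)
    R = allangles.size * mean_vector(allangles).resultant_length
    sum_Ri = float(np.sum(R_i))
    within = N - sum_Ri
    if within <= 1e-12 * N:
        raise DegenerateDispersionError(
            "zero within-group angular dispersion; F is unbounded"
        )
    rbar = sum_Ri / N
    kappa = kappa_ml(rbar)
    K = 1.0 + 3.0 / (8.0 * kappa) if math.isfinite(kappa) and kappa > 0 else 1.0
    df_between = k - 1
    df_within = N - k
    F = K * df_within * max(sum_Ri - R, 0.0) / (df_between * within)
    p = float(stats.f.sf(F, df_between, df_within))
    return WatsonWilliamsResult(
        F_statistic=float(F),
        df_between=df_between,
        df_within=df_within,
        p_value=p,
        kappa_hat=float(kappa),
        assumption_warning=kappa < KAPPA_WARN_THRESHOLD,
    )


def rayleigh_test(angles) -> tuple[float, float]:
    """Rayleigh test of angular uniformity: z = n * Rbar^2.

    Uses the standard small-sample p approximation
    p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n)) with Rn the
    unnormalized resultant length.  Requires n >= 3.
    """
    a = np.asarray(angles, dtype=float)
    n = a.size
    if n < 3:
        raise ValueError("rayleigh_test needs n >= 3")
    rbar = mean_vector(a).resultant_length
    Rn = n * rbar
    z = n * rbar**2
    p = math.exp(math.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - Rn**2)) - (1.0 + 2.0 * n))
    return float(z), float(min(p, 1.0))
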