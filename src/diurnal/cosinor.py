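"""Fixed-wavelength cosinor regression for two-day hormone profiles.

The model is the standard single-component cosinor

    Y(t) = M + A * cos(2*pi*(t - phi) / tau)

with mesor M, amplitude A >= 0, acrophase phi (reported as the clock time of
the curve maximum) and wavelength tau, fixed at 24 h for all primary fits.
With tau fixed the model is linear in M and in the rectangular coefficients
(a, b) of cos(omega*t) and sin(omega*t), so the global least-squares optimum
has a closed form: ordinary least squares followed by A = hypot(a, b) and
phi = atan2(b, a)/omega.  An equivalent sine parameterization
Y = M + A*sin(2*pi*(t - psi)/tau), used in the source analyses for cortisol,
peaks a quarter period after psi; both forms canonicalize to the same
(M, A, peak clock time), so the two hormones are directly comparable.

The free-period variant (period feature only) bounds tau to [20, 28] h and
profiles the period out by variable projection: for each candidate tau the
linear parameters are solved in closed form, and the one-dimensional SSE(tau)
is minimized by a coarse grid plus bounded scalar refinement.

Usage follows the Model/Results convention::

    model = Cosinor.from_profile(profile)           # or Cosinor(t, y)
    res = model.fit()                               # closed form, tau = 24
    res.params.acrophase_clock, res.r_squared
    res.summary()
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .data import SubjectProfile

DEFAULT_PERIOD = 24.0
PERIOD_BOUNDS = (20.0, 28.0)
#: relative amplitude below which the acrophase is reported as undefined
DEGENERATE_AMPLITUDE_RTOL = 1e-8


class InsufficientDataError(ValueError):
    """Fewer usable points than free parameters."""


class FitNotConvergedError(RuntimeError):
    """Iterative refinement failed; carries the closed-form fallback."""

    def __init__(self, message: str, fallback: "CosinorParams"):
        super().__init__(message)
        self.fallback = fallback


@dataclass(frozen=True)
class CosinorParams:
    """Canonical cosinor parameters for one fitted profile.

    ``acrophase_clock`` is the clock time (hours in [0, 24)) at which the
    fitted curve attains its maximum; it is NaN, with the
    ``acrophase_undefined`` flag set, when the amplitude is degenerate.
    ``form`` records which parameterization was requested (reporting is
    canonical either way).
    """

    mesor: float
    amplitude: float
    acrophase_clock: float
    period: float
    r_squared: float
    form: str = "cosine"
    n_used: int = 0
    flags: frozenset[str] = frozenset()

    @property
    def fitted_peak(self) -> float:
        return self.mesor + self.amplitude


def canonicalize(
    form: str,
    mesor: float,
    amplitude: float,
    phase_clock: float,
    period: float = DEFAULT_PERIOD,
) -> tuple[float, float, float]:
    """Reduce any (form, amplitude sign, phase) representation to canonical.

    Returns (mesor, amplitude >= 0, acrophase_clock in [0, 24)) where
    acrophase_clock is the clock time of the curve maximum.  A negative
    amplitude shifts the peak by half a period; the sine form peaks a quarter
    period after its phase parameter.
    """
    if form not in ("cosine", "sine"):
        raise ValueError(f"unknown cosinor form {form!r}")
    if form == "sine":
        phase_clock = phase_clock + period / 4.0
    if amplitude < 0:
        amplitude = -amplitude
        phase_clock = phase_clock + period / 2.0
    return mesor, amplitude, phase_clock % 24.0


def predict(
    params: CosinorParams, elapsed_times, anchor: float = 8.0
) -> np.ndarray:
    """Evaluate the fitted curve at elapsed hours since the day-1 anchor.

    The acrophase is stored as a clock time; on the elapsed axis the curve
    peaks at (acrophase_clock - anchor) mod 24 (and every period thereafter).
    """
    t = np.asarray(elapsed_times, dtype=float)
    if math.isnan(params.acrophase_clock):
        return np.full_like(t, params.mesor)
    peak_elapsed = (params.acrophase_clock - anchor) % 24.0
    return params.mesor + params.amplitude * np.cos(
        2.0 * np.pi * (t - peak_elapsed) / params.period
    )


def _ols_at_period(t: np.ndarray, y: np.ndarray, period: float):
    """Closed-form least squares at fixed period.

    Returns (mesor, a, b, sse) for y ~ mesor + a*cos(wt) + b*sin(wt).
    """
    omega = 2.0 * np.pi / period
    X = np.column_stack([np.ones_like(t), np.cos(omega * t), np.sin(omega * t)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef[0], coef[1], coef[2], float(resid @ resid)


class Cosinor:
    """Cosinor regression model for one timed concentration series.

    Parameters
    ----------
    elapsed_times : array-like
        Hours since the day-1 anchor sample (monotone over the two days).
    values : array-like
        Concentrations at those times (no NaNs; drop missing slots first).
    form : {"cosine", "sine"}
        Requested parameterization; results are canonical in either case.
    anchor : float
        Clock time of elapsed 0, used to map phases back to clock time.
    """

    def __init__(self, elapsed_times, values, form: str = "cosine",
                 anchor: float = 8.0):
        self.t = np.asarray(elapsed_times, dtype=float)
        self.y = np.asarray(values, dtype=float)
        if self.t.shape != self.y.shape or self.t.ndim != 1:
            raise ValueError("elapsed_times and values must be equal-length 1-d")
        if np.any(np.isnan(self.y)) or np.any(np.isnan(self.t)):
            raise ValueError("NaN in inputs; drop missing slots before fitting")
        if form not in ("cosine", "sine"):
            raise ValueError(f"unknown cosinor form {form!r}")
        self.form = form
        self.anchor = float(anchor)

    @classmethod
    def from_profile(cls, profile: SubjectProfile, form: str | None = None):
        """Build from a SubjectProfile, skipping missing slots.

        Without an explicit ``form``, cortisol uses the sine parameterization
        and melatonin the cosine one, matching the source analyses; the
        canonical output is identical either way.
        """
        if form is None:
            form = "sine" if profile.analyte == "cortisol" else "cosine"
        t, y = profile.times_values()
        return cls(t, y, form=form, anchor=profile.schedule.anchor)

    @property
    def nobs(self) -> int:
        return len(self.y)

    def _params_from_linear(
        self, mesor: float, a: float, b: float, period: float, sse: float,
        extra_flags: frozenset[str] = frozenset(),
    ) -> CosinorParams:
        amplitude = math.hypot(a, b)
        sst = float(np.sum((self.y - self.y.mean()) ** 2))
        flags = set(extra_flags)
        # constant series leave SST at rounding-noise scale, not exactly 0
        sst_floor = self.nobs * (1e-12 * max(1.0, float(np.max(np.abs(self.y))))) ** 2
        if sst <= sst_floor:
            r2 = math.nan
            flags.add("r2_undefined")
        else:
            r2 = 1.0 - sse / sst
        if amplitude <= DEGENERATE_AMPLITUDE_RTOL * max(abs(mesor), 1.0):
            flags.add("degenerate_amplitude")
            flags.add("acrophase_undefined")
            acro = math.nan
            amplitude = 0.0 if amplitude == 0.0 else amplitude
        else:
            # peak of a*cos + b*sin on the elapsed axis, then to clock time
            peak_elapsed = math.atan2(b, a) * period / (2.0 * np.pi)
            acro = (self.anchor + peak_elapsed) % 24.0
        return CosinorParams(
            mesor=float(mesor),
            amplitude=float(amplitude),
            acrophase_clock=acro,
            period=float(period),
            r_squared=r2,
            form=self.form,
            n_used=self.nobs,
            flags=frozenset(flags),
        )

    def fit(self, period: float = DEFAULT_PERIOD) -> "CosinorResults":
        """Closed-form global least-squares fit at a fixed period."""
        if self.nobs < 4:
            raise InsufficientDataError(
                f"need >= 4 non-missing points, got {self.nobs}"
            )
        if period <= 0:
            raise ValueError("period must be positive")
        mesor, a, b, sse = _ols_at_period(self.t, self.y, period)
        return CosinorResults(self, self._params_from_linear(mesor, a, b, period, sse), sse)

    def fit_nonlinear(
        self,
        period_mode: str = "fixed24",
        period_bounds: tuple[float, float] = PERIOD_BOUNDS,
    ) -> "CosinorResults":
        """Iterative least squares, initialized from the closed form.

        ``fixed24`` refines (mesor, amplitude, acrophase) at tau = 24 h and
        must agree with :meth:`fit`; ``free_bounded`` profiles the period over
        ``period_bounds`` by variable projection, so its SSE is never above
        the fixed-period SSE.  A period that optimizes at a bound is returned
        there with the ``period_at_bound`` flag.
        """
        if period_mode not in ("fixed24", "free_bounded"):
            raise ValueError(f"unknown period_mode {period_mode!r}")
        if period_mode == "free_bounded" and self.nobs < 5:
            raise InsufficientDataError(
                f"need >= 5 non-missing points for a free period, got {self.nobs}"
            )
        closed = self.fit()
        if period_mode == "fixed24":
            return self._refine_fixed(closed)
        return self._fit_free_period(closed, period_bounds)

    def _refine_fixed(self, closed: "CosinorResults") -> "CosinorResults":
        p = closed.params
        if "acrophase_undefined" in p.flags:
            return closed
        peak_elapsed = (p.acrophase_clock - self.anchor) % 24.0
        x0 = np.array([p.mesor, p.amplitude, peak_elapsed])

        def resid(x):
            return x[0] + x[1] * np.cos(
                2.0 * np.pi * (self.t - x[2]) / DEFAULT_PERIOD
            ) - self.y

        sol = optimize.least_squares(resid, x0, method="lm", xtol=1e-14,
                                     ftol=1e-14, gtol=1e-14)
        if not sol.success:
            raise FitNotConvergedError("fixed-period refinement failed", p)
        mesor, amp, peak = sol.x
        mesor, amp, acro = canonicalize(
            "cosine", mesor, amp, (self.anchor + peak) % 24.0, DEFAULT_PERIOD
        )
        sse = float(sol.fun @ sol.fun)
        omega = 2.0 * np.pi / DEFAULT_PERIOD
        a = amp * math.cos(omega * ((acro - self.anchor) % 24.0))
        b = amp * math.sin(omega * ((acro - self.anchor) % 24.0))
        return CosinorResults(
            self, self._params_from_linear(mesor, a, b, DEFAULT_PERIOD, sse), sse
        )

    def _fit_free_period(
        self, closed: "CosinorResults", bounds: tuple[float, float]
    ) -> "CosinorResults":
        lo, hi = bounds
        if not 0 < lo < hi:
            raise ValueError(f"bad period bounds {bounds}")
        grid = np.linspace(lo, hi, 33)
        if lo <= DEFAULT_PERIOD <= hi:
            grid = np.unique(np.append(grid, DEFAULT_PERIOD))
        sses = [_ols_at_period(self.t, self.y, tau)[3] for tau in grid]
        i = int(np.argmin(sses))
        blo = grid[max(i - 1, 0)]
        bhi = grid[min(i + 1, len(grid) - 1)]
        sol = optimize.minimize_scalar(
            lambda tau: _ols_at_period(self.t, self.y, tau)[3],
            bounds=(blo, bhi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        tau, sse = float(sol.x), float(sol.fun)
        if sses[i] < sse:  # guard against refinement regressions
            tau, sse = float(grid[i]), float(sses[i])
        flags = set()
        if min(tau - lo, hi - tau) < 1e-4:
            tau = lo if tau - lo < hi - tau else hi
            flags.add("period_at_bound")
        mesor, a, b, sse = _ols_at_period(self.t, self.y, tau)
        return CosinorResults(
            self,
            self._params_from_linear(mesor, a, b, tau, sse, frozenset(flags)),
            sse,
        )


class CosinorResults:
    """Fit results: canonical parameters, goodness of fit and diagnostics."""

    def __init__(self, model: Cosinor, params: CosinorParams, sse: float):
        self.model = model
        self.params = params
        self.sse = sse

    @property
    def r_squared(self) -> float:
        return self.params.r_squared

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.t)

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.fittedvalues

    def predict(self, elapsed_times) -> np.ndarray:
        return predict(self.params, elapsed_times, anchor=self.model.anchor)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Cosinor fit",
            "===========",
            f"n used            {p.n_used:>10d}",
            f"form              {p.form:>10s}",
            f"period (h)        {p.period:>10.4f}",
            f"mesor             {p.mesor:>10.4f}",
            f"amplitude         {p.amplitude:>10.4f}",
            f"acrophase (clock) {p.acrophase_clock:>10.4f}",
            f"fitted peak       {p.fitted_peak:>10.4f}",
            f"R-squared         {p.r_squared:>10.4f}",
            f"SSE               {self.sse:>10.6g}",
        ]
        if p.flags:
            lines.append(f"flags: {', '.join(sorted(p.flags))}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed points and fitted curve over the two-day elapsed axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.t, self.model.y, "o", label="observed")
        tt = np.linspace(self.model.t.min(), self.model.t.max(), 200)
        ax.plot(tt, self.predict(tt), "-", label="cosinor fit")
        ax.set_xlabel("elapsed time (h)")
        ax.set_ylabel("concentration")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# profile-level convenience wrappers

def fit_closed_form(
    profile: SubjectProfile, period: float = DEFAULT_PERIOD
) -> CosinorParams:
    """Closed-form cosinor fit of a profile at a fixed period."""
    return Cosinor.from_profile(profile).fit(period=period).params


def fit_nonlinear(
    profile: SubjectProfile,
    period_mode: str = "fixed24",
    period_bounds: tuple[float, float] = PERIOD_BOUNDS,
) -> CosinorParams:
    """Iterative cosinor fit of a profile (fixed 24 h or bounded free period)."""
    return (
        Cosinor.from_profile(profile)
        .fit_nonlinear(period_mode=period_mode, period_bounds=period_bounds)
        .params
    )


def fit_group_mean(
    profiles, period: float = DEFAULT_PERIOD, pooled: bool = False
) -> CosinorParams:
    """Cosinor fit of a group-level curve.

    By default fits the pointwise group-mean profile (one mean per scheduled
    slot, slots with no data dropped); with ``pooled`` fits all individual
    points of all profiles together.
    """
    profiles = list(profiles)
    if not profiles:
        raise InsufficientDataError("no profiles")
    anchor = profiles[0].schedule.anchor
    if pooled:
        t = np.concatenate([p.times_values()[0] for p in profiles])
        y = np.concatenate([p.times_values()[1] for p in profiles])
    else:
        slots: dict[float, list[float]] = {}
        for p in profiles:
            for s in p.present:
                slots.setdefault(s.elapsed_time, []).append(s.value)
        t = np.array(sorted(slots))
        y = np.array([np.mean(slots[e]) for e in t])
    return Cosinor(t, y, anchor=anchor).fit(period=period).params
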