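"""Cosinor fitting: closed form vs iterative, canonicalization, recovery.

The independent oracle for the closed-form fit is a brute-force grid search
over (acrophase, amplitude, mesor) refined to 1e-4; it never calls the
fitting code under test.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diurnal.cosinor import (
    Cosinor,
    CosinorParams,
    InsufficientDataError,
    canonicalize,
    fit_closed_form,
    fit_nonlinear,
    predict,
)
from diurnal.data import DEFAULT_SCHEDULE

from conftest import build_profile, cosinor_values

T = np.array(DEFAULT_SCHEDULE.elapsed_times())


def sse_at(t, y, mesor, amplitude, peak_elapsed, period=24.0):
    pred = mesor + amplitude * np.cos(2 * np.pi * (t - peak_elapsed) / period)
    return float(np.sum((y - pred) ** 2))


def grid_search_oracle(t, y, period=24.0):
    """Brute-force (acrophase x amplitude x mesor) search refined to 1e-4."""
    best = (math.inf, None)
    m_lo, m_hi = y.min(), y.max()
    a_hi = (y.max() - y.min())
    grids = (
        (np.linspace(0, 24, 97, endpoint=False),
         np.linspace(0, a_hi, 49),
         np.linspace(m_lo, m_hi, 49)),
    )
    centers = None
    for step in range(10):
        if centers is None:
            peaks, amps, mesors = grids[0]
        else:
            p0, a0, m0 = centers
            w = 24 / 96 / 2**step, a_hi / 48 / 2**step, (m_hi - m_lo) / 48 / 2**step
            peaks = p0 + np.linspace(-2, 2, 9) * w[0]
            amps = np.clip(a0 + np.linspace(-2, 2, 9) * w[1], 0, None)
            mesors = m0 + np.linspace(-2, 2, 9) * w[2]
        for pk in peaks:
            for am in amps:
                for me in mesors:
                    s = sse_at(t, y, me, am, pk, period)
                    if s < best[0]:
                        best = (s, (pk % 24.0, am, me))
        centers = best[1]
    peak_elapsed, amplitude, mesor = best[1]
    return mesor, amplitude, (DEFAULT_SCHEDULE.anchor + peak_elapsed) % 24.0


class TestClosedForm:
    def test_noiseless_recovery_exact(self, noiseless_profile):
        p = fit_closed_form(noiseless_profile)
        assert p.mesor == pytest.approx(10.0, abs=1e-9)
        assert p.amplitude == pytest.approx(5.0, abs=1e-9)
        assert p.acrophase_clock == pytest.approx(8.0, abs=1e-9)
        assert p.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_profile_degenerate(self):
        prof = build_profile([7.2] * 14)
        p = fit_closed_form(prof)
        assert p.mesor == pytest.approx(7.2)
        assert p.amplitude == pytest.approx(0.0, abs=1e-9)
        assert math.isnan(p.acrophase_clock)
        assert "acrophase_undefined" in p.flags
        assert "r2_undefined" in p.flags

    def test_matches_grid_search_oracle_on_noisy_profile(self, noisy_profile):
        t, y = map(np.asarray, noisy_profile.times_values())
        om, oa, oacro = grid_search_oracle(t, y)
        p = fit_closed_form(noisy_profile)
        assert p.mesor == pytest.approx(om, abs=1e-3)
        assert p.amplitude == pytest.approx(oa, abs=1e-3)
        assert p.acrophase_clock == pytest.approx(oacro, abs=1e-3)

    def test_insufficient_data_raises(self):
        prof = build_profile([5.0, 6.0, 7.0] + [None] * 11)
        with pytest.raises(InsufficientDataError):
            fit_closed_form(prof)

    def test_r_squared_is_one_minus_ss_ratio(self, noisy_profile):
        t, y = map(np.asarray, noisy_profile.times_values())
        res = Cosinor.from_profile(noisy_profile).fit()
        sst = np.sum((y - y.mean()) ** 2)
        assert res.r_squared == pytest.approx(1 - res.sse / sst, rel=1e-12)


class TestNonlinear:
    def test_fixed24_matches_closed_form(self, noisy_profile):
        model = Cosinor.from_profile(noisy_profile)
        closed = model.fit()
        nls = model.fit_nonlinear("fixed24")
        assert abs(nls.sse - closed.sse) <= 1e-6 * max(closed.sse, 1e-300)
        assert nls.params.acrophase_clock == pytest.approx(
            closed.params.acrophase_clock, abs=1e-6
        )

    def test_free_period_recovers_22_5(self):
        vals = cosinor_values(10.0, 5.0, 8.0, period=22.5)
        prof = build_profile(list(vals))
        p = fit_nonlinear(prof, "free_bounded")
        assert p.period == pytest.approx(22.5, abs=0.05)

    def test_free_period_sse_never_above_fixed(self, noisy_profile):
        model = Cosinor.from_profile(noisy_profile)
        assert (
            model.fit_nonlinear("free_bounded").sse
            <= model.fit().sse + 1e-12
        )

    def test_period_at_bound_flagged(self):
        # truth period 19 h lies below the [20, 28] bound
        vals = cosinor_values(10.0, 5.0, 8.0, period=19.0)
        prof = build_profile(list(vals))
        p = fit_nonlinear(prof, "free_bounded")
        assert p.period == 20.0
        assert "period_at_bound" in p.flags

    def test_free_period_needs_five_points(self):
        prof = build_profile([5.0, 6.0, 7.0, 8.0] + [None] * 10)
        with pytest.raises(InsufficientDataError):
            fit_nonlinear(prof, "free_bounded")


class TestCanonicalize:
    def test_negative_amplitude_shifts_half_period(self):
        mesor, amp, acro = canonicalize("cosine", 1.0, -3.0, 10.0)
        assert (amp, acro) == (3.0, 22.0)

    def test_sine_peaks_quarter_period_later(self):
        # sine phase 2 -> peak at clock 2 + 6 = 8
        _, _, acro = canonicalize("sine", 1.0, 3.0, 2.0)
        assert acro == 8.0

    def test_phase_wraps_modulo_24(self):
        _, _, acro = canonicalize("cosine", 1.0, 3.0, 27.0)
        assert acro == 3.0

    def test_sine_and_cosine_fits_agree(self, noisy_profile):
        p_cos = Cosinor.from_profile(noisy_profile, form="cosine").fit().params
        p_sin = Cosinor.from_profile(noisy_profile, form="sine").fit().params
        assert p_sin.acrophase_clock == pytest.approx(
            p_cos.acrophase_clock, abs=1e-9
        )
        assert p_sin.amplitude == pytest.approx(p_cos.amplitude, abs=1e-9)


class TestPredict:
    params = CosinorParams(mesor=10.0, amplitude=5.0, acrophase_clock=8.0,
                           period=24.0, r_squared=1.0)

    @pytest.mark.parametrize("clock, expected", [(8.0, 15.0), (20.0, 5.0),
                                                 (2.0, 10.0)])
    def test_peak_trough_mesor(self, clock, expected):
        elapsed = (clock - 8.0) % 24.0
        assert predict(self.params, [elapsed])[0] == pytest.approx(expected)

    def test_value_at_acrophase_is_peak_for_any_form(self, noisy_profile):
        for form in ("cosine", "sine"):
            p = Cosinor.from_profile(noisy_profile, form=form).fit().params
            peak_elapsed = (p.acrophase_clock - 8.0) % 24.0
            assert predict(p, [peak_elapsed])[0] == pytest.approx(
                p.mesor + p.amplitude
            )


class TestEquivariance:
    @given(st.floats(-30, 30))
    @settings(max_examples=25, deadline=None)
    def test_time_shift_shifts_acrophase(self, delta):
        rng = np.random.default_rng(7)
        y = cosinor_values(10, 5, 8) * (1 + rng.normal(0, 0.1, 14))
        base = Cosinor(T, y).fit().params
        shifted = Cosinor(T, y, anchor=(8.0 + delta) % 24.0).fit().params
        assert shifted.acrophase_clock == pytest.approx(
            (base.acrophase_clock + delta) % 24.0, abs=1e-9
        )
        assert shifted.mesor == pytest.approx(base.mesor, abs=1e-9)
        assert shifted.amplitude == pytest.approx(base.amplitude, abs=1e-9)
        assert shifted.r_squared == pytest.approx(base.r_squared, abs=1e-9)

    @given(st.floats(1e-3, 1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(11)
        y = cosinor_values(10, 5, 8) * (1 + rng.normal(0, 0.1, 14))
        base = Cosinor(T, y).fit().params
        scaled = Cosinor(T, c * y).fit().params
        assert scaled.mesor == pytest.approx(c * base.mesor, rel=1e-9)
        assert scaled.amplitude == pytest.approx(c * base.amplitude, rel=1e-9)
        assert scaled.acrophase_clock == pytest.approx(
            base.acrophase_clock, abs=1e-9
        )
        assert scaled.r_squared == pytest.approx(base.r_squared, abs=1e-9)


def test_summary_reports_canonical_parameters(noiseless_profile):
    res = Cosinor.from_profile(noiseless_profile).fit()
    text = res.summary()
    assert "mesor" in text and "acrophase" in text
    assert f"{res.params.amplitude:.4f}" in text
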