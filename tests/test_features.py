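"""Feature-ledger extraction: anchored maxima, slopes, two-day differences.

The deep check is a spreadsheet-style oracle: every feature of a seeded
synthetic subject recomputed directly from its 14 raw numbers with nothing
but arithmetic, then compared to extract_features.
"""

import math

import numpy as np
import pytest

from diurnal.cosinor import fit_closed_form, fit_nonlinear, predict
from diurnal.data import DEFAULT_SCHEDULE
from diurnal.features import FEATURE_NAMES, extract_features, feature_table

from conftest import build_profile, cosinor_values


def fit_pair(profile):
    return fit_closed_form(profile), fit_nonlinear(profile, "free_bounded")


class TestTwoDayDiff:
    def test_duplicated_days_give_zero(self):
        day = [3.0, 5.0, 2.0, 4.0, 6.0, 1.0, 2.5]
        prof = build_profile(day + day)
        fs = extract_features(prof, *fit_pair(prof))
        assert fs.two_day_diff == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_gives_abs_c(self):
        day = [3.0, 5.0, 2.0, 4.0, 6.0, 1.0, 2.5]
        for c in (1.7, -0.9):
            prof = build_profile(day + [v + c for v in day])
            fs = extract_features(prof, *fit_pair(prof))
            assert fs.two_day_diff == pytest.approx(abs(c), abs=1e-12)

    def test_symmetric_in_days_and_shift_invariant(self):
        rng = np.random.default_rng(0)
        d1, d2 = rng.uniform(1, 9, 7), rng.uniform(1, 9, 7)
        a = build_profile(list(d1) + list(d2))
        b = build_profile(list(d2) + list(d1))
        shifted = build_profile(list(d1 + 5.0) + list(d2 + 5.0))
        fa = extract_features(a, *fit_pair(a))
        fb = extract_features(b, *fit_pair(b))
        fc = extract_features(shifted, *fit_pair(shifted))
        assert fa.two_day_diff == pytest.approx(fb.two_day_diff, abs=1e-12)
        assert fa.two_day_diff == pytest.approx(fc.two_day_diff, abs=1e-12)

    def test_sum_variant_accumulates(self):
        day = [3.0] * 7
        prof = build_profile(day + [4.0] * 7)
        fs = extract_features(prof, *fit_pair(prof),
                              two_day_diff_stat="sum")
        assert fs.two_day_diff == pytest.approx(7.0)

    def test_missing_on_one_day_drops_the_pair(self):
        day = [3.0, 5.0, 2.0, 4.0, 6.0, 1.0, 2.5]
        values = day + [v + 1 for v in day]
        values[7] = None  # day-2 08:00 missing -> pair dropped
        prof = build_profile(values)
        fs = extract_features(prof, *fit_pair(prof))
        assert fs.two_day_diff == pytest.approx(1.0, abs=1e-12)


class TestSlopes:
    def test_exact_daytime_line(self):
        values = [6.0, 4.0, 2.0] + [1.0] * 11
        prof = build_profile(values)
        fs = extract_features(prof, *fit_pair(prof))
        assert fs.slope_day1 == pytest.approx(-2.0 / 3.0, abs=1e-12)

    def test_scaling_and_shift_behaviour(self):
        rng = np.random.default_rng(4)
        vals = list(rng.uniform(1, 9, 14))
        prof = build_profile(vals)
        scaled = build_profile([3.0 * v for v in vals])
        shifted = build_profile([v + 2.0 for v in vals])
        f0 = extract_features(prof, *fit_pair(prof))
        fsc = extract_features(scaled, *fit_pair(scaled))
        fsh = extract_features(shifted, *fit_pair(shifted))
        for name in ("slope_day1", "slope_day2", "slope_night1",
                     "slope_night2"):
            assert getattr(fsc, name) == pytest.approx(
                3.0 * getattr(f0, name), rel=1e-9
            )
            assert getattr(fsh, name) == pytest.approx(
                getattr(f0, name), abs=1e-9
            )

    def test_cortisol_night1_uses_elapsed_spacing_into_next_morning(self):
        # 01:00 -> 05:00 -> next 08:00 spans elapsed {17, 21, 24}
        values = [0.0] * 14
        values[5], values[6], values[7] = 2.0, 6.0, 9.0  # slope 1 per hour
        prof = build_profile(values)
        fs = extract_features(prof, *fit_pair(prof))
        assert fs.slope_night1 == pytest.approx(1.0, abs=1e-12)

    def test_melatonin_night_triplet_is_22_01_05(self):
        values = [0.0] * 14
        values[4], values[5], values[6] = 1.0, 4.0, 8.0  # elapsed 14, 17, 21
        prof = build_profile(values, analyte="melatonin")
        fs = extract_features(prof, *fit_pair(prof))
        assert fs.slope_night1 == pytest.approx(1.0, abs=1e-12)

    def test_cortisol_night2_is_two_point_and_degraded(self):
        # no day-3 08:00 exists, so the triplet has only two sampled points
        values = [1.0] * 14
        values[12], values[13] = 2.0, 6.0  # elapsed 41, 45
        prof = build_profile(values)
        fs = extract_features(prof, *fit_pair(prof))
        assert fs.slope_night2 == pytest.approx(1.0, abs=1e-12)
        assert "slope_night2_degraded" in fs.flags

    def test_single_point_triplet_is_missing(self):
        values = [1.0] * 14
        values[0], values[1] = None, None  # leaves one daytime point on day 1
        prof = build_profile(values)
        fs = extract_features(prof, *fit_pair(prof))
        assert fs.slope_day1 is None
        assert "slope_day1_missing" in fs.flags


class TestAnchoredMaxAndRange:
    def test_cortisol_anchor_is_day2_0800(self):
        values = list(np.arange(14.0) + 1)
        prof = build_profile(values)
        fs = extract_features(prof, *fit_pair(prof))
        assert fs.max_level == values[7]  # elapsed 24
        assert fs.range == pytest.approx(13.0)

    def test_melatonin_anchor_is_day2_0500(self):
        values = list(np.arange(14.0) + 1)
        prof = build_profile(values, analyte="melatonin")
        fs = extract_features(prof, *fit_pair(prof))
        assert fs.max_level == values[13]  # elapsed 45

    def test_missing_anchor_slot_flags(self):
        values = [5.0] * 14
        values[7] = None
        prof = build_profile(values)
        fs = extract_features(prof, *fit_pair(prof))
        assert fs.max_level is None
        assert "max_level_missing" in fs.flags

    def test_noiseless_anchor_equals_prediction(self):
        prof = build_profile(list(cosinor_values(10, 5, 8)))
        fixed = fit_closed_form(prof)
        fs = extract_features(prof, fixed, None)
        assert fs.max_level == pytest.approx(
            float(predict(fixed, [24.0])[0]), abs=1e-9
        )


class TestSpreadsheetOracle:
    def test_all_features_match_hand_recomputation(self):
        rng = np.random.default_rng(123)
        raw = cosinor_values(9.0, 4.0, 7.5) * (1 + rng.normal(0, 0.08, 14))
        raw = np.maximum(raw, 0.0)
        prof = build_profile(list(raw))
        fixed, free = fit_pair(prof)
        fs = extract_features(prof, fixed, free)
        # hand recomputation from the 14 raw numbers
        assert fs.avg_24h == pytest.approx(raw.mean(), abs=1e-12)
        assert fs.max_level == pytest.approx(raw[7], abs=1e-12)
        assert fs.range == pytest.approx(raw.max() - raw.min(), abs=1e-12)
        assert fs.two_day_diff == pytest.approx(
            np.mean(np.abs(raw[:7] - raw[7:])), abs=1e-12
        )
        e = np.array(DEFAULT_SCHEDULE.elapsed_times())
        for name, idx in (("slope_day1", [0, 1, 2]), ("slope_day2", [7, 8, 9]),
                          ("slope_night1", [5, 6, 7]),
                          ("slope_night2", [12, 13])):
            x, y = e[idx], raw[idx]
            beta = np.sum((x - x.mean()) * (y - y.mean())) / np.sum(
                (x - x.mean()) ** 2
            )
            assert getattr(fs, name) == pytest.approx(beta, abs=1e-10), name
        assert fs.fitted_mesor == pytest.approx(fixed.mesor)
        assert fs.fitted_peak == pytest.approx(fixed.mesor + fixed.amplitude)
        assert fs.acrophase_clock == pytest.approx(fixed.acrophase_clock)
        assert fs.period == pytest.approx(free.period)


class TestFeatureTable:
    def test_shape_and_column_order(self):
        rng = np.random.default_rng(6)
        profiles, fits = [], {}
        for sid in ("A", "B", "C"):
            for analyte in ("cortisol", "melatonin"):
                vals = cosinor_values(8, 3, 6) * (1 + rng.normal(0, 0.05, 14))
                p = build_profile(list(vals), subject_id=sid, analyte=analyte)
                profiles.append(p)
                fits[(sid, analyte)] = fit_pair(p)
        table = feature_table(profiles, fits)
        assert len(table) == 6
        assert list(table.columns[:3]) == ["subject_id", "group", "analyte"]
        assert list(table.columns[3:15]) == list(FEATURE_NAMES)

    def test_no_free_fit_leaves_period_empty(self, noiseless_profile):
        fixed = fit_closed_form(noiseless_profile)
        table = feature_table([noiseless_profile],
                              {("S1", "cortisol"): (fixed, None)})
        assert math.isnan(table["period"].iloc[0])

    def test_orphan_fit_is_consistency_error(self, noiseless_profile):
        fixed = fit_closed_form(noiseless_profile)
        with pytest.raises(ValueError, match="not in profiles"):
            feature_table([noiseless_profile],
                          {("S1", "cortisol"): (fixed, None),
                           ("GHOST", "cortisol"): (fixed, None)})
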