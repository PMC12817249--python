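"""Synthetic-cohort generator: circadian structure, stress kernels,
pulse morphology, scale anchors and the depression-cohort layout."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stressci import cohort
from stressci.errors import ConfigError, InvalidParameterError


class TestCortisol:
    def test_peak_at_acrophase(self, profile, minute_grid):
        series = cohort.simulate_cortisol_diurnal(profile, minute_grid, 0.0, 0)
        t_peak = minute_grid[np.argmax(series)]
        assert abs(t_peak - profile.acrophase) <= 1.0 / 60.0

    def test_inverted_schedule_is_12h_circular_shift(self, profile, minute_grid):
        inv = profile.with_inverted_schedule()
        normal = cohort.simulate_cortisol_diurnal(
            profile, (minute_grid - 12.0) % 24.0, 0.0, 0)
        inverted = cohort.simulate_cortisol_diurnal(inv, minute_grid, 0.0, 0)
        np.testing.assert_allclose(inverted, normal)

    def test_zero_amplitude_gives_constant_basal(self, profile):
        flat = dataclasses.replace(profile, amplitude_cortisol=0.0)
        series = cohort.simulate_cortisol_diurnal(flat, [2.0, 9.0, 15.0], 0.0, 0)
        np.testing.assert_allclose(series, flat.basal_cortisol)

    def test_24h_periodicity(self, profile):
        t = np.linspace(0.0, 23.99, 97)
        a = cohort.cortisol_day_curve(profile, t)
        b = cohort.cortisol_day_curve(profile, t + 24.0)
        np.testing.assert_allclose(a, b)

    def test_seed_determinism(self, profile, minute_grid):
        a = cohort.simulate_cortisol_diurnal(profile, minute_grid, 5.0, 42)
        b = cohort.simulate_cortisol_diurnal(profile, minute_grid, 5.0, 42)
        assert np.array_equal(a, b)

    def test_invalid_profile_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            cohort.SubjectProfile(subject_id="bad", basal_cortisol=np.nan)
        with pytest.raises(InvalidParameterError):
            cohort.SubjectProfile(subject_id="bad", acrophase=24.0)

    def test_coffee_habit_raises_cortisol_only(self, profile):
        coffee = dataclasses.replace(profile, coffee_habit=True)
        t = [9.0, 13.0]
        lifted = cohort.simulate_cortisol_diurnal(coffee, t, 0.0, 0)
        plain = cohort.simulate_cortisol_diurnal(profile, t, 0.0, 0)
        np.testing.assert_allclose(
            lifted, plain * (1.0 + cohort.COFFEE_CORTISOL_UPLIFT))
        st_a, hr_a = cohort.simulate_st_hr(coffee, t, 0.0, 0.0, 0)
        st_b, hr_b = cohort.simulate_st_hr(profile, t, 0.0, 0.0, 0)
        np.testing.assert_array_equal(st_a, st_b)
        np.testing.assert_array_equal(hr_a, hr_b)

    @settings(max_examples=25, deadline=None)
    @given(noise_sd=st.floats(0.0, 50.0), seed=st.integers(0, 2 ** 20))
    def test_series_strictly_positive_and_finite(self, noise_sd, seed):
        prof = cohort.SubjectProfile(subject_id="H")
        t = np.linspace(0.0, 23.5, 48)
        series = cohort.simulate_cortisol_diurnal(prof, t, noise_sd, seed)
        assert np.all(np.isfinite(series)) and np.all(series > 0)


class TestGlucose:
    def test_no_meals_constant_basal(self, profile):
        series = cohort.simulate_glucose(profile, [9.0, 12.0], meal_times=[],
                                         noise_sd=0.0)
        np.testing.assert_allclose(series, profile.basal_glucose)

    def test_peak_follows_meal_by_rise_time(self, profile, minute_grid):
        series = cohort.simulate_glucose(profile, minute_grid, meal_times=[12.0],
                                         noise_sd=0.0)
        t_peak = minute_grid[np.argmax(series)]
        assert abs(t_peak - (12.0 + cohort.GLUCOSE_PULSE_RISE_H)) <= 1.0 / 60.0

    def test_two_far_apart_meals_superpose(self, profile, minute_grid):
        series = cohort.simulate_glucose(profile, minute_grid,
                                         meal_times=[8.0, 18.0], noise_sd=0.0)
        in_win = lambda lo, hi: (minute_grid >= lo) & (minute_grid < hi)
        peak1 = series[in_win(8.0, 13.0)].max()
        peak2 = series[in_win(18.0, 23.0)].max()
        assert abs(peak1 - peak2) / peak2 < 0.01

    def test_negative_meal_amplitude_rejected(self, profile):
        with pytest.raises(InvalidParameterError):
            cohort.simulate_glucose(profile, [12.0], meal_amplitude=-1.0)


class TestStHr:
    def test_noiseless_constants(self, profile):
        st_s, hr_s = cohort.simulate_st_hr(profile, [9.0, 15.0, 21.0])
        np.testing.assert_allclose(st_s, profile.basal_st)
        np.testing.assert_allclose(hr_s, profile.basal_hr)

    def test_exercise_habit_lowers_hr_by_offset(self, profile):
        runner = dataclasses.replace(profile, exercise_habit=True)
        _, hr_a = cohort.simulate_st_hr(runner, [10.0] * 50, 0.0, 2.0, seed=3)
        _, hr_b = cohort.simulate_st_hr(profile, [10.0] * 50, 0.0, 2.0, seed=3)
        assert np.mean(hr_b) - np.mean(hr_a) == pytest.approx(
            cohort.EXERCISE_HR_OFFSET)


class TestStressInjection:
    times = np.arange(8.0, 14.0, 1.0 / 60.0)

    def _flat_series(self):
        return {b: np.full(self.times.size, 100.0) for b in cohort.BIOMARKERS}

    def test_zero_intensity_is_identity(self):
        event = cohort.StressEvent(onset=10.0, intensity=0.0)
        out = cohort.inject_stress_response(self.times, self._flat_series(), event)
        for b in cohort.BIOMARKERS:
            np.testing.assert_array_equal(out[b], self._flat_series()[b])

    def test_glucose_peak_lags_cortisol_by_lag_difference(self):
        event = cohort.StressEvent(onset=10.0)
        out = cohort.inject_stress_response(self.times, self._flat_series(), event)
        t_c = self.times[np.argmax(out["cortisol"])]
        t_g = self.times[np.argmax(out["glucose"])]
        expected = (event.lag["glucose"] - event.lag["cortisol"]) / 60.0
        assert t_g - t_c == pytest.approx(expected, abs=1.5 / 60.0)

    def test_no_anticipatory_effect(self):
        event = cohort.StressEvent(onset=10.0)
        out = cohort.inject_stress_response(self.times, self._flat_series(), event)
        for b in cohort.BIOMARKERS:
            pre = self.times < 10.0 + event.lag[b] / 60.0
            np.testing.assert_array_equal(out[b][pre], 100.0)

    def test_relative_deviation_decays_below_1pct(self):
        event = cohort.StressEvent(onset=8.5, duration=15.0, decay_halflife=15.0)
        out = cohort.inject_stress_response(self.times, self._flat_series(), event)
        dev = out["cortisol"] / 100.0 - 1.0
        tail = self.times > 8.5 + (15.0 + 5.0) / 60.0 + 8 * 15.0 / 60.0
        assert np.all(dev[tail] < 0.01 * dev.max())

    def test_unknown_biomarker_key_rejected(self):
        event = cohort.StressEvent(onset=10.0, gain={"lactate": 1.0})
        with pytest.raises(KeyError):
            cohort.inject_stress_response(self.times, self._flat_series(), event)


class TestPulseTrace:
    def test_beat_spacing_at_60_bpm(self):
        trace = cohort.simulate_pulse_trace(60.0, 30.0, 1000.0, snr_db=np.inf)
        np.testing.assert_allclose(np.diff(trace.true_beat_times), 1.0)

    def test_beat_count_at_72_bpm(self):
        trace = cohort.simulate_pulse_trace(72.0, 30.0, 1000.0, snr_db=np.inf)
        assert abs(len(trace.true_beat_times) - 36) <= 1

    def test_snr_power_ratio(self):
        clean = cohort.simulate_pulse_trace(72.0, 30.0, 1000.0, snr_db=np.inf)
        noisy = cohort.simulate_pulse_trace(72.0, 30.0, 1000.0, snr_db=10.0, seed=5)
        noise = noisy.values - clean.values
        ratio = np.var(clean.values) / np.var(noise)
        assert ratio == pytest.approx(10.0, rel=0.05)

    def test_parameter_validation(self):
        with pytest.raises(InvalidParameterError):
            cohort.simulate_pulse_trace(20.0, 30.0)
        with pytest.raises(InvalidParameterError):
            cohort.simulate_pulse_trace(60.0, 5.0)
        with pytest.raises(InvalidParameterError):
            cohort.simulate_pulse_trace(60.0, 30.0, sample_rate=30.0)


class TestScaleScores:
    @pytest.mark.parametrize("kind", sorted(cohort.SCALES))
    def test_zero_latent_hits_minimum_anchor(self, kind):
        score = cohort.generate_scale_scores(0.0, kind, 0.0, 0)
        assert score == cohort.scale_bounds(kind)[0]

    @pytest.mark.parametrize("kind", sorted(cohort.SCALES))
    def test_monotone_in_latent(self, kind):
        lo = cohort.generate_scale_scores(0.5, kind, 0.0, 0)
        hi = cohort.generate_scale_scores(2.5, kind, 0.0, 0)
        assert lo < hi

    def test_stais_levels_straddle_cutpoints(self):
        low, mid, high = (float(cohort.generate_scale_scores(l, "STAIS", 0.0, 0))
                          for l in (1.0, 2.0, 3.0))
        assert low < 34.0 <= mid < 44.0 <= high

    def test_unknown_kind_rejected(self):
        with pytest.raises(InvalidParameterError):
            cohort.generate_scale_scores(1.0, "PHQ9")


class TestDepressionCohort:
    def test_default_design_layout(self):
        table = cohort.generate_depression_cohort(seed=0)
        assert len(table) == 147
        subjects = table.drop_duplicates("subject_id")
        patient = subjects["group"].isin(["MD", "SD"]).sum()
        assert patient == 23 and len(subjects) - patient == 26
        assert table.groupby("subject_id").size().eq(3).all()

    def test_seed_reproducibility(self):
        a = cohort.generate_depression_cohort(seed=11)
        b = cohort.generate_depression_cohort(seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_group_effect_rejected(self):
        with pytest.raises(ConfigError):
            cohort.CohortDesign(group_counts={"ND": 5, "XX": 5})

    def test_biomarkers_positive(self):
        table = cohort.generate_depression_cohort(seed=4)
        for b in cohort.BIOMARKERS:
            assert (table[b] > 0).all()
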