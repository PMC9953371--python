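"""Tests of cohort generation, trial execution and error statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as scipy_stats

from sdrvitals import (
    BandSpec,
    NoiseSpec,
    Subject,
    TrialResult,
    VitalProfile,
    drop_outliers,
    error_stats,
    generate_cohort,
    run_trial,
)
from sdrvitals.evaluation import manual_count_rr


def make_result(sid, rr_err=0.0, hr_err=0.0):
    return TrialResult(
        subject_id=sid,
        measured_rr=15.0 + rr_err,
        measured_hr=72.0 + hr_err,
        reference_rr=15.0,
        reference_hr=72.0,
    )


class TestGenerateCohort:
    def test_default_cohort_respects_covariate_ranges(self):
        cohort = generate_cohort(20, seed=1)
        assert len(cohort) == 20
        for s in cohort:
            assert 123.0 <= s.weight_lb <= 285.8
            assert 57.0 <= s.height_in <= 73.0
            assert 29.0 <= s.age_yr <= 79.0
            assert 12.0 <= s.profile.rr_bpm <= 25.0
            assert 55.0 <= s.profile.hr_bpm <= 120.0

    def test_n20_gender_split_is_8_male_12_female(self):
        cohort = generate_cohort(20, seed=3)
        genders = [s.gender for s in cohort]
        assert genders.count("male") == 8
        assert genders.count("female") == 12

    def test_same_seed_reproduces_cohort(self):
        assert generate_cohort(5, seed=9) == generate_cohort(5, seed=9)

    def test_empty_cohort(self):
        assert generate_cohort(0, seed=1) == []

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            generate_cohort(5, seed=1, weight_range=(300.0, 100.0))


class TestRunTrial:
    def test_noiseless_subject_is_recovered_accurately(self):
        s = Subject(
            id="C1", weight_lb=150, height_in=65, age_yr=40, gender="male",
            posture="Good", profile=VitalProfile(rr_bpm=14.3, hr_bpm=83.7),
            noise=NoiseSpec(seed=0),
        )
        r = run_trial(s, duration=60.0, window_length=30.0)
        assert abs(r.rr_error) <= 0.2
        assert abs(r.hr_error) <= 0.5

    def test_heart_filter_cutoff_outlier_mechanism(self):
        # a tachycardic subject at 120 BPM (2 Hz): with the heart-band high
        # cutoff at 2.0 Hz the heart line is attenuated and a respiration
        # harmonic captures the peak; raising the cutoff to 2.5 Hz recovers it
        profile = VitalProfile(
            rr_bpm=18, hr_bpm=120, resp_harmonic_weights=(1.0, 0, 0, 0.05)
        )
        s = Subject(
            id="T1", weight_lb=160, height_in=64, age_yr=55, gender="female",
            posture="Good", profile=profile,
            noise=NoiseSpec(thermal_std=1e-4, phase_walk_std=1e-3, seed=7),
        )
        low = run_trial(s, duration=60.0, window_length=30.0)
        assert abs(low.hr_error) > 5.0
        high = run_trial(
            s, duration=60.0, window_length=30.0, hr_band=BandSpec(0.8, 2.5, "heart")
        )
        assert abs(high.hr_error) <= 3.0

    def test_bad_posture_degrades_accuracy_on_matched_seeds(self):
        profile = VitalProfile(rr_bpm=17, hr_bpm=80)
        noise = NoiseSpec(thermal_std=4e-5, phase_walk_std=1e-3, seed=21)
        results = {}
        for posture in ("Good", "Bad"):
            s = Subject(
                id="P1", weight_lb=140, height_in=62, age_yr=35, gender="female",
                posture=posture, profile=profile, noise=noise,
            )
            results[posture] = run_trial(s, duration=60.0, window_length=30.0)
        assert abs(results["Bad"].hr_error) >= abs(results["Good"].hr_error)
        assert abs(results["Bad"].rr_error) >= abs(results["Good"].rr_error)

    def test_duration_shorter_than_window_rejected(self):
        s = generate_cohort(1, seed=1)[0]
        with pytest.raises(ValueError, match="window_length"):
            run_trial(s, duration=10.0, window_length=30.0)


class TestErrorStats:
    def test_identical_errors(self):
        results = [make_result(f"S{k}", rr_err=0.5, hr_err=0.5) for k in range(3)]
        stats = error_stats(results)
        s = stats.groups["all"]["rr_error"]
        assert s.median == pytest.approx(0.5)
        assert s.std == pytest.approx(0.0)

    def test_hand_computed_median_and_std(self):
        errs = [1.0, 2.0, 3.0, 4.0, 10.0]
        results = [make_result(f"S{k}", hr_err=e) for k, e in enumerate(errs)]
        s = error_stats(results).groups["all"]["hr_error"]
        assert s.median == pytest.approx(3.0)
        assert s.std == pytest.approx(3.5355, abs=1e-3)
        assert s.five_number[0] == 1.0 and s.five_number[4] == 10.0

    def test_agrees_with_brute_force_summaries(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            errs = rng.normal(0, 3, rng.integers(2, 15))
            results = [make_result(f"S{k}", hr_err=e) for k, e in enumerate(errs)]
            s = error_stats(results).groups["all"]["hr_error"]
            # brute-force median: midpoint of the sorted values
            v = sorted(errs)
            n = len(v)
            med = v[n // 2] if n % 2 else (v[n // 2 - 1] + v[n // 2]) / 2
            mean = sum(v) / n
            var = sum((e - mean) ** 2 for e in v) / (n - 1)
            assert s.median == pytest.approx(med, abs=1e-12)
            assert s.std == pytest.approx(math.sqrt(var), rel=1e-12)
            assert s.five_number[1] <= s.median <= s.five_number[3]

    def test_gender_grouping_partitions_cohort(self):
        cohort = generate_cohort(20, seed=2)
        results = [make_result(s.id, hr_err=k * 0.1) for k, s in enumerate(cohort)]
        stats = error_stats(results, group_by="gender", subjects=cohort)
        assert sum(g["hr_error"].n for g in stats.groups.values()) == 20
        assert set(stats.groups) == {"male", "female"}

    def test_numeric_grouping_with_edges_partitions_cohort(self):
        cohort = generate_cohort(20, seed=2)
        results = [make_result(s.id) for s in cohort]
        stats = error_stats(
            results, group_by="weight", subjects=cohort, bin_edges=[123, 200, 286]
        )
        assert sum(g["rr_error"].n for g in stats.groups.values()) == 20

    def test_unknown_covariate_rejected(self):
        cohort = generate_cohort(2, seed=1)
        results = [make_result(s.id) for s in cohort]
        with pytest.raises(ValueError, match="unknown grouping"):
            error_stats(results, group_by="shoe_size", subjects=cohort)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            error_stats([])


class TestCovariateNullEffect:
    def test_no_covariate_drives_error_in_default_generator(self, lab_experiment):
        # the generator ties accuracy to noise, not body covariates, so
        # absolute errors must not regress on weight/height/age
        abs_rr = np.abs([r.rr_error for r in lab_experiment.results])
        abs_hr = np.abs([r.hr_error for r in lab_experiment.results])
        for attr in ("weight_lb", "height_in", "age_yr"):
            x = np.array([getattr(s, attr) for s in lab_experiment.subjects])
            for errors in (abs_rr, abs_hr):
                fit = scipy_stats.linregress(x, errors)
                assert fit.pvalue > 0.01

    def test_heart_errors_exceed_respiration_errors_in_median(self, lab_experiment):
        abs_rr = np.abs([r.rr_error for r in lab_experiment.results])
        abs_hr = np.abs([r.hr_error for r in lab_experiment.results])
        assert np.median(abs_hr) >= np.median(abs_rr)


class TestDropOutliers:
    def test_rule_none_is_identity(self):
        results = [make_result(f"S{k}", hr_err=k) for k in range(5)]
        assert drop_outliers(results, "none") == results

    def test_max_abs_hr_removes_exactly_the_worst(self):
        errs = [2.0, -1.0, 43.0, 0.5, -7.0]
        results = [make_result(f"S{k}", hr_err=e) for k, e in enumerate(errs)]
        kept = drop_outliers(results, "max-abs-hr")
        assert len(kept) == 4
        assert all(abs(r.hr_error) != 43.0 for r in kept)

    def test_removing_clinical_style_outlier_tightens_spread(self):
        # one grossly wrong HR among otherwise moderate errors
        errs = [1.0, -2.0, 3.0, 0.5, -43.0, 2.5]
        results = [make_result(f"S{k}", hr_err=e) for k, e in enumerate(errs)]
        before = error_stats(results).groups["all"]["hr_error"].std
        after = error_stats(drop_outliers(results, "max-abs-hr"))
        assert after.groups["all"]["hr_error"].std < before

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=-50, max_value=50), min_size=2, max_size=8))
    def test_always_removes_a_maximal_error(self, errs):
        results = [make_result(f"S{k}", hr_err=e) for k, e in enumerate(errs)]
        kept = drop_outliers(results, "max-abs-hr")
        assert len(kept) == len(results) - 1
        if kept:
            assert max(abs(r.hr_error) for r in kept) <= max(abs(e) for e in errs)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="unknown outlier rule"):
            drop_outliers([make_result("S0")], "median-trim")


class TestManualCountReference:
    @pytest.mark.parametrize("rr,expected", [(15.0, 15.0), (14.4, 14.0), (14.6, 15.0)])
    def test_rounds_to_whole_breaths_per_minute(self, rr, expected):
        assert manual_count_rr(rr) == expected

    def test_shorter_count_window_coarsens_quantisation(self):
        assert manual_count_rr(14.4, count_duration=30.0) == 14.0
        with pytest.raises(ValueError):
            manual_count_rr(-1.0)
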