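import math

import numpy as np
import pandas as pd
import pytest

from vitd_pbpk.config import HOURS_PER_YEAR
from vitd_pbpk.errors import ConfigurationError, DataError, InvalidInputError
from vitd_pbpk.predict import predict_child
from vitd_pbpk.records import ChildRecord
from vitd_pbpk.simulation import (
    PercentileBand,
    build_virtual_cohort,
    compliance,
    coverage_metrics,
    daily_regimen,
    load_percentile_table,
    prediction_intervals,
    sample_between_percentiles,
    scenario_modify,
    threshold_attainment,
    weekly_regimen,
)


class TestPercentileSampler:
    def test_single_percentile_table(self):
        draws = sample_between_percentiles({50: 55.0}, 20000, (10.0, 90.0), seed_or_rng=1)
        assert draws.min() >= 10.0 and draws.max() <= 90.0
        assert np.median(draws) == pytest.approx(55.0, abs=1.0)

    def test_empty_draw(self):
        assert sample_between_percentiles({50: 55.0}, 0, (10, 90)).size == 0

    def test_bounds_respected_for_any_seed(self):
        tab = {5: 31.0, 25: 44.0, 50: 55.0, 75: 66.0, 95: 81.0}
        for seed in range(5):
            draws = sample_between_percentiles(tab, 1000, (10, 90), seed)
            assert draws.min() >= 10 and draws.max() <= 90

    def test_non_monotone_table_rejected(self):
        with pytest.raises(DataError):
            sample_between_percentiles({25: 50.0, 50: 45.0}, 10, (0, 100))

    def test_bounds_must_enclose_values(self):
        with pytest.raises(DataError):
            sample_between_percentiles({50: 55.0}, 10, (60.0, 90.0))

    def test_empirical_percentiles_match_table(self):
        tab = {5: 31.0, 25: 44.0, 50: 55.0, 75: 66.0, 95: 81.0}
        draws = sample_between_percentiles(tab, 100_000, (10, 90), 7)
        for p, v in tab.items():
            # the fraction of draws below the tabulated value is the
            # nominal percentile, within 1.5 points
            assert 100.0 * np.mean(draws < v) == pytest.approx(p, abs=1.5)


class TestVirtualCohort:
    def test_reproducible_and_sex_balanced(self):
        a = build_virtual_cohort("6y", 60, seed=3)
        b = build_virtual_cohort("6y", 60, seed=3)
        assert [c.wt0 for c in a] == [c.wt0 for c in b]
        assert sum(c.sex == "boy" for c in a) == 30

    def test_6y_weight_within_table_bounds(self):
        cohort = build_virtual_cohort("6y", 200, seed=1)
        wts = np.array([c.wt0 for c in cohort])
        assert wts.min() > 10 and wts.max() < 40
        c25 = np.array([c.baseline_c25 for c in cohort])
        assert c25.min() >= 10 and c25.max() <= 90

    def test_11y_weight_is_bmi_times_height_squared(self):
        # spot-check the BMI x height^2 construction at the medians
        bmi = load_percentile_table("bmi_11y", "boys")
        ht = load_percentile_table("height_11y", "boys")
        assert 17.0 * 1.45 ** 2 == pytest.approx(35.74, abs=0.01)
        cohort = build_virtual_cohort("11y", 300, seed=2)
        wts = np.array([c.wt0 for c in cohort])
        lo = 0.8 * bmi.iloc[0] * (0.9 * ht.iloc[0]) ** 2
        hi = 1.35 * bmi.iloc[-1] * (1.1 * ht.iloc[-1]) ** 2
        assert wts.min() >= lo * 0.99 and wts.max() <= hi * 1.01

    def test_11y_cohort_heavier_than_6y(self):
        w6 = np.mean([c.wt0 for c in build_virtual_cohort("6y", 200, seed=4)])
        w11 = np.mean([c.wt0 for c in build_virtual_cohort("11y", 200, seed=4)])
        assert w11 > w6 + 5

    def test_unknown_age_group(self):
        with pytest.raises(ConfigurationError):
            build_virtual_cohort("9y", 10)


def _constant_band(value, n_weeks=10):
    times = np.arange(n_weeks + 1) * 168.0
    arr = np.full((3, times.size), float(value))
    return PercentileBand(
        times_h=times, levels=(2.5, 50.0, 97.5),
        percentiles=arr, pi_lo=arr - 1.0, pi_hi=arr + 1.0,
    )


class TestThresholdAttainment:
    def test_already_above_attains_at_week_zero(self):
        assert threshold_attainment(_constant_band(60.0), 50.0) == 0.0

    def test_never_crossing_reports_not_attained(self):
        assert threshold_attainment(_constant_band(40.0), 50.0) is None

    def test_first_crossing_reported(self):
        band = _constant_band(40.0)
        band.percentiles[0, 6:] = 55.0
        assert threshold_attainment(band, 50.0) == 6.0


class TestScenarioModify:
    def test_four_fold_clearance(self, truth_population):
        pop = scenario_modify(truth_population, clmax_multiplier=4.0)
        ratio = math.exp(pop.theta["clmax"]) / math.exp(truth_population.theta["clmax"])
        assert ratio == pytest.approx(4.0, rel=1e-12)
        # 0.012 1/h scaled 4-fold reaches the 0.048 1/h scenario value
        assert math.exp(pop.theta["clmax"]) == pytest.approx(0.048, abs=1e-3)

    def test_identity(self, truth_population):
        pop = scenario_modify(truth_population, clmax_multiplier=1.0)
        assert pop.theta == truth_population.theta

    def test_c50_override_reaches_simulator(self, truth_population):
        pop = scenario_modify(truth_population, c50_override=10.0)
        assert pop.config.c50 == 10.0

    def test_final_concentration_monotone_decreasing_in_clearance(
        self, truth_population
    ):
        # reference scenario child: 30 kg, baseline 50 nmol/L, 250 ug/week
        child = ChildRecord(
            id="ref", wt0=30.0, wt_final=30.0, zbmi=0.0, baseline_c25=50.0,
            dose_times_h=np.arange(156) * 168.0,
            dose_amounts_ug=np.full(156, 250.0),
        )
        t = np.array([3 * HOURS_PER_YEAR])
        finals = []
        for mult in (0.5, 1.0, 2.0, 4.0):
            pop = scenario_modify(truth_population, clmax_multiplier=mult)
            finals.append(predict_child(pop, child, None, t, baseline_c25=50.0)[0])
        assert np.all(np.diff(finals) < 0)


class TestPredictionIntervals:
    def test_degenerate_band_without_variability(self, truth_population):
        pop = truth_population.replace(
            omega={"clmax": 0.0}, sigma_add=0.0, sigma_prop=0.0, theta_se={}
        )
        child = ChildRecord(id=1, wt0=30.0, wt_final=39.0, baseline_c25=64.7)
        times = np.arange(0, 5000, 500.0)
        regimen = weekly_regimen(250.0, 30)
        band = prediction_intervals(
            child, regimen, pop,
            n_studies=3, n_samples=50, seed=0, times_h=times,
        )
        pred = predict_child(pop, child, None, times, doses=regimen)
        for i in range(3):
            np.testing.assert_allclose(band.percentiles[i], pred, rtol=1e-6)
            np.testing.assert_allclose(band.pi_lo[i], band.pi_hi[i], rtol=1e-9)

    def test_percentiles_ordered_everywhere(self, truth_population):
        child = ChildRecord(id=1, wt0=25.0, wt_final=34.0, baseline_c25=45.0)
        times = np.arange(0, 52 * 168.0, 168.0 * 4)
        band = prediction_intervals(
            child, daily_regimen(24.4, 364), truth_population,
            n_studies=4, n_samples=200, seed=9, times_h=times,
        )
        assert np.all(band.level(2.5) <= band.level(50.0) + 1e-12)
        assert np.all(band.level(50.0) <= band.level(97.5) + 1e-12)
        assert np.all(band.pi_lo <= band.pi_hi + 1e-12)

    def test_band_width_shrinks_with_baseline_weight(self, truth_population):
        # heavier children have larger distribution volumes, so the same
        # dosing produces a narrower spread of attained concentrations
        times = np.array([0.0, 3 * HOURS_PER_YEAR])
        widths = []
        for wt in (20.0, 35.0, 50.0):
            child = ChildRecord(
                id=1, wt0=wt, wt_final=wt + 9.0, baseline_c25=55.0
            )
            band = prediction_intervals(
                child, weekly_regimen(250.0, 156), truth_population,
                n_studies=5, n_samples=300, seed=2, times_h=times,
            )
            widths.append(band.level(97.5)[-1] - band.level(2.5)[-1])
        assert widths[0] > widths[1] > widths[2]


class TestPredictionIntervalCoverage:
    def test_nominal_coverage_on_self_generated_data(self):
        # per-child 2.5th-97.5th bands simulated at the generating truth
        # should cover ~95% of post-baseline observations; the band must
        # sample the full observation model (incl. proportional error)
        # for nominal coverage of noisy data
        from vitd_pbpk.synthetic import TrialDesign, simulate_trial

        trial = simulate_trial(TrialDesign(n_children=100), seed=404)
        pop = trial.truth
        inside = total = 0
        for child in trial.children:
            mask = child.fit_mask()
            times = child.obs_times_h[mask]
            band = prediction_intervals(
                child, None, pop, n_studies=5, n_samples=400, seed=7,
                times_h=times, include_proportional_error=True,
            )
            y = child.obs_dv[mask]
            obs = pd.DataFrame({"time_h": times, "dv": y})
            cov = coverage_metrics(obs, band)
            inside += cov["pct_within_pi"] / 100.0 * cov["n"]
            total += cov["n"]
        assert total >= 300
        assert 90.0 <= 100.0 * inside / total <= 99.0


class TestCoverageMetrics:
    def test_counts_inside_outer_band(self):
        band = _constant_band(60.0)
        obs = pd.DataFrame(
            {"time_h": np.arange(10) * 168.0,
             "dv": [60.0] * 8 + [200.0, 300.0]}
        )
        out = coverage_metrics(obs, band)
        assert out["pct_within_pi"] == pytest.approx(80.0)

    def test_zero_error_when_obs_equal_median(self):
        band = _constant_band(60.0)
        obs = pd.DataFrame({"time_h": [0.0, 168.0], "dv": [60.0, 60.0]})
        out = coverage_metrics(obs, band)
        assert out["mean_error"] == 0.0


class TestCompliance:
    @pytest.mark.parametrize(
        "received, weeks, expected",
        [(120, 156, 76.9), (156, 156, 100.0), (0, 156, 0.0)],
    )
    def test_examples(self, received, weeks, expected):
        assert compliance(received, weeks) == pytest.approx(expected, abs=0.05)

    def test_bounds_enforced(self):
        with pytest.raises(InvalidInputError):
            compliance(200, 156)
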