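import math

import numpy as np
import pytest
from scipy import stats

from vitd_pbpk.errors import DataError, InvalidInputError
from vitd_pbpk.estimation import (
    SaemSettings,
    cwres,
    eta_shrinkage_from_ebes,
    fit,
    fit_seasonal_baseline,
    information_criteria,
    linear_scale_report,
    loglikelihood,
    npde,
    vpc,
)
from vitd_pbpk.population import final_model_population, residual_variance
from vitd_pbpk.predict import EtaGridInterpolator, predict_child
from vitd_pbpk.records import ChildRecord
from vitd_pbpk.synthetic import TrialDesign, simulate_trial


class TestLinearScaleReport:
    def test_clmax_row(self):
        est, (lo, hi), rse = linear_scale_report(-4.43, 0.0787)
        assert est == pytest.approx(0.0119, abs=1e-4)
        assert lo == pytest.approx(0.0102, abs=1e-4)
        assert hi == pytest.approx(0.0139, abs=1e-4)
        assert rse == pytest.approx(1.78, abs=0.01)

    def test_kp25fm_row(self):
        est, (lo, hi), _ = linear_scale_report(1.54, 0.136)
        assert est == pytest.approx(4.66, abs=0.01)
        assert lo == pytest.approx(3.6, abs=0.05)
        assert hi == pytest.approx(6.11, rel=0.01)

    def test_zero_theta_has_undefined_rse(self):
        est, (lo, hi), rse = linear_scale_report(0.0, 0.1)
        assert est == 1.0
        assert lo == pytest.approx(math.exp(-0.196))
        assert math.isnan(rse)

    def test_negative_se_rejected(self):
        with pytest.raises(InvalidInputError):
            linear_scale_report(1.0, -0.1)


class TestInformationCriteria:
    def test_closed_form(self):
        aic, bic = information_criteria(-100.0, 4, 300)
        assert aic == pytest.approx(208.0)
        assert bic == pytest.approx(-2 * -100 + 4 * math.log(300))

    def test_zero_params(self):
        aic, bic = information_criteria(-50.0, 0, 10)
        assert aic == bic == 100.0

    def test_requires_observations(self):
        with pytest.raises(InvalidInputError):
            information_criteria(-1.0, 1, 0)


class TestEtaShrinkage:
    def test_no_shrinkage_when_ebe_sd_matches_omega(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(0, 1, 4000)
        draws = (draws - draws.mean()) / draws.std() * math.sqrt(0.332)
        ebes = {i: np.array([e]) for i, e in enumerate(draws)}
        out = eta_shrinkage_from_ebes(ebes, {"clmax": 0.332}, ("clmax",))
        assert out["clmax"] == pytest.approx(0.0, abs=1e-9)

    def test_published_shrinkage_ratio(self):
        ebes = {0: np.array([0.869]), 1: np.array([-0.869])}
        out = eta_shrinkage_from_ebes(ebes, {"clmax": 1.0}, ("clmax",))
        assert out["clmax"] == pytest.approx(13.1, abs=0.1)

    def test_total_shrinkage_when_all_ebes_zero(self):
        ebes = {i: np.array([0.0]) for i in range(5)}
        out = eta_shrinkage_from_ebes(ebes, {"clmax": 0.332}, ("clmax",))
        assert out["clmax"] == pytest.approx(100.0)

    def test_zero_omega_not_applicable(self):
        out = eta_shrinkage_from_ebes({0: np.array([0.1])}, {"clmax": 0.0}, ("clmax",))
        assert math.isnan(out["clmax"])


class TestSeasonalBaseline:
    def test_noise_free_recovery(self):
        t = np.linspace(0, 2, 40)
        y = 60 + 11.5 * np.sin(2 * np.pi * t + 1.0)
        m, a, phi = fit_seasonal_baseline(t, y)
        assert m == pytest.approx(60.0, abs=1e-6)
        assert a == pytest.approx(11.5, abs=1e-6)
        assert phi == pytest.approx(1.0, abs=1e-6)

    def test_constant_series_zero_amplitude(self):
        t = np.linspace(0, 1, 10)
        m, a, _ = fit_seasonal_baseline(t, np.full(10, 55.0))
        assert m == pytest.approx(55.0)
        assert a == 0.0

    def test_canonical_nonnegative_amplitude(self):
        t = np.linspace(0, 1.5, 30)
        y = 50 - 8.0 * np.sin(2 * np.pi * t + 0.4)  # negative-amplitude form
        m, a, phi = fit_seasonal_baseline(t, y)
        assert a == pytest.approx(8.0, abs=1e-8)
        assert phi == pytest.approx((0.4 + math.pi) % (2 * math.pi), abs=1e-8)
        np.testing.assert_allclose(m + a * np.sin(2 * np.pi * t + phi), y, atol=1e-8)

    def test_degenerate_design_rejected(self):
        with pytest.raises(DataError):
            fit_seasonal_baseline([0.1, 0.1, 0.1, 0.1], [1, 2, 3, 4])


class TestLikelihood:
    def test_zero_omega_matches_closed_form_gaussian(self, truth_population):
        pop = truth_population.replace(omega={"clmax": 0.0})
        trial = simulate_trial(TrialDesign(n_children=4, truth=pop), seed=3)
        ll = loglikelihood(trial.children, pop)
        direct = 0.0
        for child in trial.children:
            mask = child.fit_mask()
            f = predict_child(pop, child, None, child.obs_times_h[mask])
            var = residual_variance(f, pop.sigma_add, pop.sigma_prop)
            y = child.obs_dv[mask]
            direct += float(
                np.sum(-0.5 * ((y - f) ** 2 / var + np.log(2 * np.pi * var)))
            )
        assert ll == pytest.approx(direct, abs=1e-6)

    def test_quadrature_beats_mode_only_approximation(self, small_trial):
        # the AGQ marginal likelihood must dominate the prior-at-zero bound
        pop = small_trial.truth
        ll = loglikelihood(small_trial.children, pop)
        assert np.isfinite(ll)
        pop0 = pop.replace(omega={"clmax": 1e-12})
        ll0 = loglikelihood(small_trial.children, pop0)
        assert ll > ll0  # integrating over IIV explains the spread better


class TestEtaGridInterpolator:
    def test_matches_direct_solves(self, truth_population, annual_visits_h):
        child = ChildRecord(
            id=1, wt0=28.0, wt_final=37.5, zbmi=0.4, baseline_c25=60.0,
            dose_times_h=np.arange(100) * 168.0,
            dose_amounts_ug=np.full(100, 250.0),
        )
        interp = EtaGridInterpolator(truth_population, child, annual_visits_h)
        for e in (-1.1, -0.3, 0.0, 0.55, 1.3):
            direct = predict_child(
                truth_population, child, {"clmax": e}, annual_visits_h
            )
            np.testing.assert_allclose(interp(e), direct, rtol=2e-3)


class TestSaemFit:
    def test_same_seed_same_data_identical_estimates(self, small_trial):
        children = small_trial.children[:5]
        s = SaemSettings(n_burn=8, n_iter=6, n_chains=1, seed=3, compute_se=False)
        r1 = fit(children, 10, s)
        r2 = fit(children, 10, s)
        assert r1.population.theta == r2.population.theta
        assert r1.population.omega == r2.population.omega
        assert r1.population.sigma_prop == r2.population.sigma_prop

    def test_zero_variability_data_recovers_theta(self, truth_population):
        truth = truth_population.replace(
            omega={"clmax": 0.0}, sigma_add=0.0, sigma_prop=0.0
        )
        trial = simulate_trial(TrialDesign(n_children=6, truth=truth), seed=8)
        s = SaemSettings(n_burn=80, n_iter=50, n_chains=1, seed=1, compute_se=False)
        res = fit(trial.children, 10, s, estimate=("clmax",))
        assert res.population.theta["clmax"] == pytest.approx(
            truth.theta["clmax"], abs=0.02
        )
        assert res.population.omega["clmax"] < 0.01
        assert res.population.sigma_prop < 0.05

    def test_unknown_estimate_name_rejected(self, small_trial):
        with pytest.raises(DataError):
            fit(small_trial.children[:2], 10, SaemSettings(n_burn=1, n_iter=1),
                estimate=("kp25_rb",))


class TestCwres:
    def test_single_observation_child(self, truth_population):
        child = ChildRecord(
            id=1, wt0=30.0, wt_final=39.0, baseline_c25=64.7,
            dose_times_h=np.arange(52) * 168.0, dose_amounts_ug=np.full(52, 250.0),
            obs_times_h=np.array([0.0, 8766.0]), obs_dv=np.array([64.7, 80.0]),
        )
        table = cwres(truth_population, [child])
        assert len(table) == 1
        assert np.isfinite(table["cwres"]).all()

    def test_misspecified_clearance_biases_cwres(self):
        # a 2x clearance error is partly absorbed by the CLmax random
        # effect per child, so the reliable residual signature is a
        # systematic location shift of the FOCE-linearised CWRES
        from vitd_pbpk.simulation import scenario_modify

        trial = simulate_trial(TrialDesign(n_children=40), seed=1)
        wrong = scenario_modify(trial.truth, clmax_multiplier=2.0)
        table = cwres(wrong, trial.children)
        _, p_value = stats.ttest_1samp(table["cwres"], 0.0)
        assert p_value < 0.05
        assert table["cwres"].mean() > 0.25

    def test_true_model_roughly_standardised(self, small_trial):
        table = cwres(small_trial.truth, small_trial.children)
        assert abs(table["cwres"].mean()) < 0.4  # loose at n = 48
        assert 0.6 < table["cwres"].std(ddof=1) < 1.4


class TestNpde:
    def test_extreme_observation_hits_boundary_rule(self, truth_population):
        child = ChildRecord(
            id=1, wt0=30.0, wt_final=39.0, baseline_c25=64.7,
            dose_times_h=np.arange(52) * 168.0, dose_amounts_ug=np.full(52, 250.0),
            obs_times_h=np.array([0.0, 8766.0]), obs_dv=np.array([64.7, 500.0]),
        )
        table = npde(truth_population, [child], nsim=100, seed=0)
        expected = stats.norm.ppf(1 - 1 / 200)
        assert table["npde"].iloc[0] == pytest.approx(expected)

    def test_minimum_nsim_enforced(self, truth_population):
        with pytest.raises(InvalidInputError):
            npde(truth_population, [], nsim=50)

    def test_true_model_npde_not_grossly_nonnormal(self, small_trial):
        table = npde(small_trial.truth, small_trial.children, nsim=400, seed=5)
        _, p = stats.shapiro(table["npde"])
        assert p > 0.01


class TestVpc:
    def test_zero_variability_collapses_to_prediction(self, truth_population):
        pop = truth_population.replace(
            omega={"clmax": 0.0}, sigma_add=0.0, sigma_prop=0.0
        )
        trial = simulate_trial(TrialDesign(n_children=3, truth=pop), seed=4)
        res = vpc(pop, trial.children, nsim=100, seed=0)
        t = res.table
        for _, row in t.iterrows():
            assert row["pi_lo"] == pytest.approx(row["pi_hi"], rel=1e-9)
        # all simulated percentiles equal the deterministic predictions,
        # which equal the observations for zero-noise data
        sel = t[t["percentile"] == 50.0]
        np.testing.assert_allclose(sel["observed"], sel["simulated"], rtol=1e-9)

    def test_seed_reproducibility(self, small_trial):
        a = vpc(small_trial.truth, small_trial.children, nsim=80, seed=11).table
        b = vpc(small_trial.truth, small_trial.children, nsim=80, seed=11).table
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())
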