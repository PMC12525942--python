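import numpy as np
import pytest

from vitd_pbpk.config import HOURS_PER_WEEK, HOURS_PER_YEAR, ug_to_nmol
from vitd_pbpk.errors import ConfigurationError, InvalidInputError
from vitd_pbpk.pbpk import (
    DoseEvent,
    PbpkParameters,
    PhysiologyPlan,
    calibrate_endogenous_input,
    clearance_rate_constant,
    derivatives,
    n_states,
    qss_vitamin_d,
    simulate_individual,
)
from vitd_pbpk.physiology import build_physiology


class TestClearanceRateConstant:
    def test_half_maximal_at_c50(self):
        assert clearance_rate_constant(30.0, 0.0119, 30.0, 1.0) == pytest.approx(
            0.0119 / 2
        )

    def test_saturates_at_clmax(self):
        assert clearance_rate_constant(1e9, 0.0119, 30.0, 1.0) == pytest.approx(
            0.0119, rel=1e-6
        )

    def test_zero_at_zero(self):
        assert clearance_rate_constant(0.0, 0.0119, 30.0, 2.0) == 0.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidInputError):
            clearance_rate_constant(-1.0, 0.0119, 30.0, 1.0)


class TestQssVitaminD:
    def test_flow_conservation_equalises_concentrations(self):
        ph = build_physiology(30.0, 0.0)
        a_art, _ = qss_vitamin_d(ph.v_ven * 10.0, ph, kp_rb=0.5)
        assert a_art / ph.v_art == pytest.approx(10.0, rel=1e-12)

    def test_zero_maps_to_zero(self):
        ph = build_physiology(30.0, 0.0)
        assert qss_vitamin_d(0.0, ph, 0.5) == (0.0, 0.0)

    def test_rest_of_body_partitioning(self):
        # V_rb = 26.83 L at 30 kg (no split); Kp 0.5, art/ven at 10 nmol/L
        ph = build_physiology(30.0, 0.0, variant_split=False)
        _, a_rb = qss_vitamin_d(ph.v_ven * 10.0, ph, kp_rb=0.5)
        assert a_rb == pytest.approx(ph.v_rb * 0.5 * 10.0, rel=1e-12)
        assert a_rb == pytest.approx(134.15, abs=0.2)


class TestDerivatives:
    def test_all_zero_state_stays_zero_without_input(self):
        ph = build_physiology(30.0, 0.0)
        p = PbpkParameters(endog=0.0)
        dy = derivatives(np.zeros(n_states(False, True)), 0.0, p, ph)
        assert np.all(dy == 0.0)

    def test_vitamin_d_mass_balance_telescopes(self):
        # d(total D)/dt = endog - CL_H * C_liver / Kp_l  (no dosing term here)
        ph = build_physiology(30.0, 0.0)
        p = PbpkParameters(endog=3.0)
        rng = np.random.default_rng(5)
        y = rng.uniform(1.0, 50.0, n_states(False, True))
        dy = derivatives(y, 0.0, p, ph)
        c_liver = y[3] / ph.v_liver
        assert dy[:5].sum() == pytest.approx(
            3.0 - p.cl_h * c_liver / p.kp_l, rel=1e-10
        )

    def test_no_conversion_decays_25ohd(self):
        # with f_m -> 0 the 25(OH)D subsystem has no source and must decay
        plan = PhysiologyPlan.fixed(30.0, 0.0)
        p = PbpkParameters(f_m=1e-12)
        _, y0 = calibrate_endogenous_input(80.0, PbpkParameters(), plan, reduced=True)
        t = np.linspace(0, HOURS_PER_YEAR, 6)
        c = simulate_individual(p, plan, [], t, reduced=True, y0=y0)
        assert np.all(np.diff(c) < 0)
        assert c[-1] < 0.5 * c[0]


class TestCalibration:
    def test_zero_baseline_zero_input(self):
        plan = PhysiologyPlan.fixed(30.0, 0.0)
        endog, y0 = calibrate_endogenous_input(0.0, PbpkParameters(), plan)
        assert endog == 0.0
        assert np.all(y0 == 0.0)

    def test_monotone_in_baseline(self):
        plan = PhysiologyPlan.fixed(30.0, 0.0)
        p = PbpkParameters()
        grid = np.linspace(10, 120, 12)
        endogs = [calibrate_endogenous_input(b, p, plan)[0] for b in grid]
        assert np.all(np.diff(endogs) > 0)

    def test_holds_baseline_without_dosing(self, reference_child):
        p, plan, y0 = reference_child
        t = np.linspace(0.0, 3 * HOURS_PER_YEAR, 7)
        c = simulate_individual(p, plan, [], t, reduced=True, y0=y0)
        assert np.all(np.abs(c - 64.7) / 64.7 < 0.005)

    def test_full_mode_initial_state_is_steady(self):
        plan = PhysiologyPlan.fixed(30.0, 0.0)
        p0 = PbpkParameters()
        endog, y0 = calibrate_endogenous_input(64.7, p0, plan, reduced=False)
        p = p0.replace(endog=endog)
        dy = derivatives(y0, 0.0, p, plan.at(0.0))
        assert np.all(np.abs(dy) < 1e-8)


class TestSimulateIndividual:
    def test_fast_matches_reference(self, reference_child, weekly_doses_3y):
        p, plan, y0 = reference_child
        t = np.linspace(0.0, 3 * HOURS_PER_YEAR, 5)
        ref = simulate_individual(p, plan, weekly_doses_3y, t, y0=y0)
        fast = simulate_individual(p, plan, weekly_doses_3y, t, y0=y0, backend="fast")
        assert np.max(np.abs(fast - ref) / ref) < 5e-3

    @pytest.mark.parametrize("dose_ug", [0.0, 250.0, 1000.0])
    def test_reduced_matches_full(self, reference_child, dose_ug):
        p, plan, y0r = reference_child
        _, y0f = calibrate_endogenous_input(64.7, p, plan, reduced=False)
        doses = [DoseEvent(i * HOURS_PER_WEEK, dose_ug) for i in range(156)]
        t = np.linspace(0.0, 3 * HOURS_PER_YEAR, 5)
        red = simulate_individual(p, plan, doses, t, reduced=True, y0=y0r)
        full = simulate_individual(p, plan, doses, t, reduced=False, y0=y0f)
        assert np.max(np.abs(red - full) / full) < 0.01

    def test_dose_exposure_sublinearity(self, reference_child):
        p, plan, y0 = reference_child
        t = np.array([3 * HOURS_PER_YEAR])

        def delta(dose_ug):
            doses = [DoseEvent(i * HOURS_PER_WEEK, dose_ug) for i in range(156)]
            return (
                simulate_individual(p, plan, doses, t, y0=y0, backend="fast")[0]
                - 64.7
            )

        assert delta(500.0) < 2.0 * delta(250.0)

    def test_steady_state_monotone_in_dose_and_clmax(self, reference_child):
        p, plan, y0 = reference_child
        t = np.array([3 * HOURS_PER_YEAR])

        def final(dose_ug, clmax):
            pp0 = p.replace(clmax=clmax, endog=0.0)
            endog, y00 = calibrate_endogenous_input(64.7, pp0, plan)
            pp = pp0.replace(endog=endog)
            doses = [DoseEvent(i * HOURS_PER_WEEK, dose_ug) for i in range(156)]
            return simulate_individual(pp, plan, doses, t, y0=y00, backend="fast")[0]

        by_dose = [final(d, 0.0119) for d in (100, 250, 500, 750)]
        assert np.all(np.diff(by_dose) > 0)
        by_clmax = [final(250, c) for c in (0.006, 0.0119, 0.024, 0.048)]
        assert np.all(np.diff(by_clmax) < 0)

    def test_mass_conservation_full_model(self, reference_child):
        # cumulative input - cumulative elimination == total amount, within 0.1%
        p0, plan, _ = reference_child
        endog, y0 = calibrate_endogenous_input(64.7, p0, plan, reduced=False)
        p = p0.replace(endog=endog)
        doses = [DoseEvent(i * HOURS_PER_WEEK, 250.0) for i in range(52)]
        t_end = HOURS_PER_YEAR
        _, states = simulate_individual(
            p, plan, doses, np.array([0.0, t_end]), reduced=False, y0=y0,
            return_states=True, rtol=1e-10, atol=1e-12,
        )
        y_end = states[t_end]
        # exact vitamin D balance fixes the cumulative hepatic elimination;
        # a fraction f_m of it is the only 25(OH)D source, whose own
        # (smooth) elimination flux is integrated on a fine grid
        d_in = ug_to_nmol(250.0) * len(doses) + endog * t_end
        delta_d = y_end[:5].sum() - y0[:5].sum()
        elim_d_total = d_in - delta_d
        grid = np.linspace(0.0, t_end, 2001)
        _, st = simulate_individual(
            p, plan, doses, grid, reduced=False, y0=y0, return_states=True,
            rtol=1e-10, atol=1e-12,
        )
        ph = plan.at(0.0)
        ys = np.array([st[g] for g in grid])
        c25v = ys[:, 6] / ph.v_ven
        from vitd_pbpk.pbpk import clearance_rate_constant

        elim_25 = clearance_rate_constant(c25v, p.clmax, p.c50, p.gamma) * ys[:, 6]
        delta_25 = y_end[5:].sum() - y0[5:].sum()
        expected_elim25 = p.f_m * elim_d_total - delta_25
        assert np.trapezoid(elim_25, grid) == pytest.approx(expected_elim25, rel=1e-3)

    def test_nonnegative_states(self, reference_child, weekly_doses_3y):
        p, plan, y0 = reference_child
        t = np.linspace(0.0, 3 * HOURS_PER_YEAR, 40)
        _, states = simulate_individual(
            p, plan, weekly_doses_3y, t, y0=y0, backend="fast", return_states=True
        )
        assert states.min() > -1e-10

    def test_unsorted_obs_rejected(self, reference_child):
        p, plan, y0 = reference_child
        with pytest.raises(InvalidInputError):
            simulate_individual(p, plan, [], np.array([2.0, 1.0]), y0=y0)

    def test_fast_backend_requires_reduced(self, reference_child):
        p, plan, _ = reference_child
        with pytest.raises(ConfigurationError):
            simulate_individual(
                p, plan, [], np.array([1.0]), reduced=False, backend="fast"
            )


def test_dose_event_unit_conversion():
    assert DoseEvent(0.0, 250.0).amount_nmol == pytest.approx(650.0, rel=2e-3)
    with pytest.raises(InvalidInputError):
        DoseEvent(-1.0, 250.0)
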