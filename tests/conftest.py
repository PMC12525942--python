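import numpy as np
import pytest

from vitd_pbpk.config import HOURS_PER_WEEK, HOURS_PER_YEAR
from vitd_pbpk.pbpk import (
    DoseEvent,
    PbpkParameters,
    PhysiologyPlan,
    calibrate_endogenous_input,
)
from vitd_pbpk.population import final_model_population
from vitd_pbpk.synthetic import TrialDesign, simulate_trial


@pytest.fixture(scope="session")
def reference_child():
    """A 30 kg, ZBMI 0 child at steady state at 64.7 nmol/L (reduced mode)."""
    p0 = PbpkParameters()
    plan = PhysiologyPlan.fixed(30.0, 0.0, split=True)
    endog, y0 = calibrate_endogenous_input(64.7, p0, plan, reduced=True)
    return p0.replace(endog=endog), plan, y0


@pytest.fixture(scope="session")
def weekly_doses_3y():
    return [DoseEvent(i * HOURS_PER_WEEK, 250.0) for i in range(156)]


@pytest.fixture(scope="session")
def truth_population():
    return final_model_population()


@pytest.fixture(scope="session")
def small_trial():
    """A 16-child synthetic trial at the published truth (shared, read-only)."""
    return simulate_trial(TrialDesign(n_children=16), seed=2024)


@pytest.fixture(scope="session")
def annual_visits_h():
    return np.array([0.0, 1.0, 2.0, 3.0]) * HOURS_PER_YEAR
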