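"""Three years of weekly 250 ug vitamin D3 in one child.

Calibrates the endogenous vitamin D supply so the child starts in
steady state at 64.7 nmol/L, then integrates the PBPK system over a
weekly dosing record, comparing the quasi-steady-state (QSS) reduced
system against the full ODE system and showing the saturable
dose-exposure relationship.
"""

import numpy as np

from vitd_pbpk.config import HOURS_PER_WEEK, HOURS_PER_YEAR
from vitd_pbpk.pbpk import (
    DoseEvent,
    PbpkParameters,
    PhysiologyPlan,
    calibrate_endogenous_input,
    simulate_individual,
)
from vitd_pbpk.physiology import WeightTrajectory

# a 30 kg child growing to 39.5 kg over the 3-year study
plan = PhysiologyPlan(
    WeightTrajectory(mode="individual_interpolated", wt0=30.0, wt_final=39.5),
    zbmi=0.0,
)
p0 = PbpkParameters()
endog, y0 = calibrate_endogenous_input(64.7, p0, plan, reduced=True)
p = p0.replace(endog=endog)
print(f"calibrated endogenous input: {endog:.2f} nmol/h "
      f"({endog * 24 * 384.64 / 1000:.1f} ug/day equivalent)")

doses = [DoseEvent(i * HOURS_PER_WEEK, 250.0) for i in range(156)]
years = np.array([0.0, 1.0, 2.0, 3.0])
t = years * HOURS_PER_YEAR

reduced = simulate_individual(p, plan, doses, t, reduced=True, y0=y0)
_, y0f = calibrate_endogenous_input(64.7, p0, plan, reduced=False)
full = simulate_individual(p, plan, doses, t, reduced=False, y0=y0f)
print("\nyear   QSS-reduced   full ODE   (serum 25(OH)D, nmol/L)")
for yr, r, f in zip(years, reduced, full):
    print(f"{yr:4.0f}   {r:11.1f}   {f:8.1f}")
print(f"max relative difference: {np.max(np.abs(reduced - full) / full):.2e}")
print("-> the QSS reduction is indistinguishable on the annual scale")

print("\ndose doubling (steady state at 3 y, weight held at 30 kg so "
      "growth dilution does not confound the comparison):")
plan30 = PhysiologyPlan.fixed(30.0, 0.0)
endog30, y030 = calibrate_endogenous_input(64.7, p0, plan30, reduced=True)
p30 = p0.replace(endog=endog30)
for dose in (250.0, 500.0):
    ds = [DoseEvent(i * HOURS_PER_WEEK, dose) for i in range(156)]
    c = simulate_individual(p30, plan30, ds, t[-1:], y0=y030, backend="fast")[0]
    print(f"  {dose:5.0f} ug/week -> {c:6.1f} nmol/L (delta {c - 64.7:+.1f})")
print("-> doubling the dose less than doubles the increment: clearance "
      "saturates")
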