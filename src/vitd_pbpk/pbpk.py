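"""Structural PBPK model for vitamin D3 and 25(OH)D in one individual.

Vitamin D occupies five compartments (GI tract, arterial blood, venous
blood, liver, rest of body); it is absorbed from the GI tract into the
liver, where a fraction ``f_m`` (default 0.33) of hepatic elimination
reappears as newly formed 25(OH)D. 25(OH)D distributes through the same
blood/liver scaffold with the non-eliminating organs either lumped
(rest of body) or split into fat mass and lean mass, and is cleared from
venous blood with a saturable, sigmoidal rate constant

    CL(C) = CLmax * C^gamma / (C50^gamma + C^gamma)          [1/h]

so the elimination flux is CL(C25_ven) * A25_ven. A constant zero-order
endogenous input (cutaneous synthesis + diet) enters venous blood; it is
calibrated so each child starts at steady state at their observed
baseline 25(OH)D.

Two integration modes exist:

* ``reduced=False`` — the full ODE system;
* ``reduced=True`` — a quasi-steady-state (QSS) reduction in which the
  arterial and rest-of-body vitamin D amounts are algebraic functions of
  the venous amount; the three pools are integrated as one mass-conserving
  lumped state and re-split at output.

Amounts are in nmol, doses at the interface in ug of vitamin D3
(250 ug = 650 nmol), concentrations in nmol/L, time in hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .config import DEFAULT_CONFIG, ModelConfig, ug_to_nmol
from .errors import (
    CalibrationError,
    ConfigurationError,
    InvalidInputError,
    SolverError,
)
from .physiology import PhysiologySet, WeightTrajectory, build_physiology, weight_at

__all__ = [
    "PbpkParameters",
    "DoseEvent",
    "PhysiologyPlan",
    "clearance_rate_constant",
    "qss_vitamin_d",
    "derivatives",
    "calibrate_endogenous_input",
    "simulate_individual",
]


@dataclass(frozen=True)
class PbpkParameters:
    """Structural-model constants and fitted values for one individual.

    ``clmax`` is referenced to ``clmax_wt_ref`` kg and scales with body
    weight as (WT/ref)^clmax_exponent; set the exponent to 0 for a
    weight-independent clearance (base-model behaviour).
    """

    clmax: float = 0.0119          # 1/h at clmax_wt_ref
    c50: float = 30.0              # nmol/L
    gamma: float = 1.0
    f_m: float = 0.33
    cl_h: float = 20.0             # L/h
    ka: float = 0.25               # 1/h
    kp_rb: float = 0.5             # vitamin D rest-of-body
    kp_l: float = 1.0              # vitamin D liver
    kp25_l: float = 1.0            # 25(OH)D liver (fixed at 1)
    kp25_fm: float = 4.66
    kp25_lm: float = 4.0
    kp25_rb: float = 4.48
    endog: float = 0.0             # nmol/h, zero-order vitamin D input
    clmax_wt_ref: float = 30.0
    clmax_exponent: float = 0.75

    def __post_init__(self):
        for name in (
            "clmax", "c50", "gamma", "cl_h", "ka", "kp_rb", "kp_l",
            "kp25_l", "kp25_fm", "kp25_lm", "kp25_rb", "clmax_wt_ref",
        ):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be strictly positive")
        if not 0 < self.f_m <= 1:
            raise InvalidInputError("f_m must be in (0, 1]")
        if self.endog < 0:
            raise InvalidInputError("endog must be >= 0")

    def replace(self, **kwargs) -> "PbpkParameters":
        return replace(self, **kwargs)

    @classmethod
    def from_config(cls, config: ModelConfig, **kwargs) -> "PbpkParameters":
        base = dict(
            c50=config.c50, gamma=config.gamma, f_m=config.f_m, cl_h=config.cl_h,
            ka=config.ka, kp_rb=config.kp_rb, kp_l=config.kp_l, kp25_l=config.kp25_l,
            kp25_fm=config.kp25_fm, kp25_lm=config.kp25_lm, kp25_rb=config.kp25_rb,
            clmax_wt_ref=config.weight_ref,
        )
        base.update(kwargs)
        return cls(**base)


@dataclass(frozen=True)
class DoseEvent:
    """One oral vitamin D3 dose: time in hours, amount in micrograms."""

    time_h: float
    amount_ug: float

    def __post_init__(self):
        if self.time_h < 0:
            raise InvalidInputError(f"dose time must be >= 0, got {self.time_h}")
        if self.amount_ug < 0:
            raise InvalidInputError(f"dose amount must be >= 0, got {self.amount_ug}")

    @property
    def amount_nmol(self) -> float:
        return ug_to_nmol(self.amount_ug)


@dataclass(frozen=True)
class PhysiologyPlan:
    """Physiology as a function of time: weight trajectory + baseline ZBMI.

    The fat-mass fraction is evaluated once at the baseline ZBMI; volume
    fractions are constant, so only total weight varies with time.
    """

    trajectory: WeightTrajectory
    zbmi: float = 0.0
    split: bool = True
    config: ModelConfig = field(default_factory=lambda: DEFAULT_CONFIG)

    @classmethod
    def fixed(
        cls,
        weight: float,
        zbmi: float = 0.0,
        split: bool = True,
        config: ModelConfig = DEFAULT_CONFIG,
    ) -> "PhysiologyPlan":
        return cls(WeightTrajectory(mode="fixed", wt0=weight), zbmi, split, config)

    def weight_at_hours(self, t_h: float) -> float:
        from .config import HOURS_PER_YEAR

        return weight_at(self.trajectory, t_h / HOURS_PER_YEAR, self.config)

    def at(self, t_h: float) -> PhysiologySet:
        return build_physiology(self.weight_at_hours(t_h), self.zbmi, self.split, self.config)


def clearance_rate_constant(c25: float, clmax: float, c50: float, gamma: float):
    """Sigmoidal 25(OH)D clearance rate constant CLmax*C^g/(C50^g + C^g) (1/h)."""
    c25 = np.asarray(c25, dtype=float)
    if np.any(c25 < 0):
        raise InvalidInputError("c25 must be >= 0")
    cg = np.power(c25, gamma)
    out = np.where(cg > 0, clmax * cg / (c50 ** gamma + cg), 0.0)
    return float(out) if out.ndim == 0 else out


def qss_vitamin_d(a_ven: float, phys: PhysiologySet, kp_rb: float):
    """Quasi-steady-state arterial and rest-of-body vitamin D amounts.

    A_art = (A_ven/V_ven) * (Q_co/(Q_l+Q_rb)) * V_art and
    A_rb = (V_rb*Kp_rb/V_art) * A_art; with flow conservation the arterial
    concentration equals the venous concentration.
    """
    if a_ven < 0:
        raise InvalidInputError("a_ven must be >= 0")
    if phys.v_ven <= 0 or phys.v_art <= 0:
        raise ConfigurationError("blood volumes must be positive")
    a_art = (a_ven / phys.v_ven) * (phys.q_co / (phys.q_liver + phys.q_rb)) * phys.v_art
    a_rb = (phys.v_rb * kp_rb / phys.v_art) * a_art
    return a_art, a_rb


# ---------------------------------------------------------------------------
# full-model state layout
# ---------------------------------------------------------------------------
# split:      [GI, Dart, Dven, Dliv, Drb, 25art, 25ven, 25liv, 25fm, 25lm]
# non-split:  [GI, Dart, Dven, Dliv, Drb, 25art, 25ven, 25liv, 25rb]


def n_states(reduced: bool, split: bool) -> int:
    if reduced:
        return 8 if split else 7
    return 10 if split else 9


def derivatives(
    state: np.ndarray,
    t: float,
    p: PbpkParameters,
    phys: PhysiologySet,
    dose_rate: float = 0.0,
) -> np.ndarray:
    """Time derivative of the full (non-reduced) state vector.

    ``dose_rate`` is an optional zero-order GI input (nmol/h); dosing in
    :func:`simulate_individual` instead applies instantaneous GI increments.
    The weight used for allometric clearance is the physiology's own
    total volume (1 kg/L density).
    """
    y = np.asarray(state, dtype=float)
    split = phys.split
    if y.size != n_states(False, split):
        raise InvalidInputError(f"expected {n_states(False, split)} states, got {y.size}")
    wt = phys.total_volume  # density 1 kg/L
    clmax_t = p.clmax * (wt / p.clmax_wt_ref) ** p.clmax_exponent
    dy = np.empty_like(y)

    gi, a_dart, a_dven, a_dliv, a_drb = y[:5]
    c_dart = a_dart / phys.v_art
    c_dven = a_dven / phys.v_ven
    c_dliv = a_dliv / phys.v_liver
    c_drb = a_drb / phys.v_rb
    dy[0] = -p.ka * gi + dose_rate
    dy[1] = phys.q_co * (c_dven - c_dart)
    dy[3] = phys.q_liver * (c_dart - c_dliv / p.kp_l) + p.ka * gi - p.cl_h * c_dliv / p.kp_l
    dy[4] = phys.q_rb * (c_dart - c_drb / p.kp_rb)
    dy[2] = (
        phys.q_liver * c_dliv / p.kp_l
        + phys.q_rb * c_drb / p.kp_rb
        - phys.q_co * c_dven
        + p.endog
    )

    prod25 = p.f_m * p.cl_h * c_dliv / p.kp_l
    a25art, a25ven, a25liv = y[5], y[6], y[7]
    c25a = a25art / phys.v_art
    c25v = a25ven / phys.v_ven
    c25l = a25liv / phys.v_liver
    cl25 = clearance_rate_constant(max(c25v, 0.0), clmax_t, p.c50, p.gamma)
    dy[5] = phys.q_co * (c25v - c25a)
    dy[7] = phys.q_liver * (c25a - c25l / p.kp25_l) + prod25
    if split:
        a25fm, a25lm = y[8], y[9]
        c25fm = a25fm / phys.v_fm
        c25lm = a25lm / phys.v_lm
        q_fm, q_lm = phys.q_fm, phys.q_lm
        dy[8] = q_fm * (c25a - c25fm / p.kp25_fm)
        dy[9] = q_lm * (c25a - c25lm / p.kp25_lm)
        tissues_return = q_fm * c25fm / p.kp25_fm + q_lm * c25lm / p.kp25_lm
    else:
        a25rb = y[8]
        c25rb = a25rb / phys.v_rb
        dy[8] = phys.q_rb * (c25a - c25rb / p.kp25_rb)
        tissues_return = phys.q_rb * c25rb / p.kp25_rb
    dy[6] = (
        phys.q_liver * c25l / p.kp25_l
        + tissues_return
        - phys.q_co * c25v
        - cl25 * a25ven
    )
    return dy


def _reduced_rhs(y, t, p: PbpkParameters, phys: PhysiologySet, wt: float):
    """RHS of the QSS-reduced system (lumped vitamin D ven+art+rb pool)."""
    split = phys.split
    clmax_t = p.clmax * (wt / p.clmax_wt_ref) ** p.clmax_exponent
    dy = np.empty_like(y)
    r = phys.q_co / (phys.q_liver + phys.q_rb)
    denom = 1.0 + r * (phys.v_art + phys.v_rb * p.kp_rb) / phys.v_ven
    gi, a_dtot, a_dliv = y[0], y[1], y[2]
    a_dven = a_dtot / denom
    c_dven = a_dven / phys.v_ven
    c_dart = r * c_dven
    c_dliv = a_dliv / phys.v_liver
    dy[0] = -p.ka * gi
    dy[2] = phys.q_liver * (c_dart - c_dliv / p.kp_l) + p.ka * gi - p.cl_h * c_dliv / p.kp_l
    dy[1] = p.endog + phys.q_liver * (c_dliv / p.kp_l - c_dart)

    prod25 = p.f_m * p.cl_h * c_dliv / p.kp_l
    a25art, a25ven, a25liv = y[3], y[4], y[5]
    c25a = a25art / phys.v_art
    c25v = a25ven / phys.v_ven
    c25l = a25liv / phys.v_liver
    cl25 = clearance_rate_constant(max(c25v, 0.0), clmax_t, p.c50, p.gamma)
    dy[3] = phys.q_co * (c25v - c25a)
    dy[5] = phys.q_liver * (c25a - c25l / p.kp25_l) + prod25
    if split:
        a25fm, a25lm = y[6], y[7]
        c25fm = a25fm / phys.v_fm
        c25lm = a25lm / phys.v_lm
        dy[6] = phys.q_fm * (c25a - c25fm / p.kp25_fm)
        dy[7] = phys.q_lm * (c25a - c25lm / p.kp25_lm)
        ret = phys.q_fm * c25fm / p.kp25_fm + phys.q_lm * c25lm / p.kp25_lm
    else:
        a25rb = y[6]
        c25rb = a25rb / phys.v_rb
        dy[6] = phys.q_rb * (c25a - c25rb / p.kp25_rb)
        ret = phys.q_rb * c25rb / p.kp25_rb
    dy[4] = phys.q_liver * c25l / p.kp25_l + ret - phys.q_co * c25v - cl25 * a25ven
    return dy


def calibrate_endogenous_input(
    baseline_c25: float,
    p: PbpkParameters,
    phys: PhysiologySet | PhysiologyPlan,
    reduced: bool = True,
):
    """Endogenous vitamin D input balancing the no-dose model at baseline.

    At the flow-limited steady state the 25(OH)D elimination flux equals
    the hepatic formation flux f_m * endog, which gives the closed form

        endog = CL(c25) * c25 * V_ven / f_m            [nmol/h]

    Returns ``(endog, state0)`` where ``state0`` is the steady initial
    state vector consistent with the requested mode (reduced/full) at the
    baseline physiology.
    """
    if baseline_c25 < 0:
        raise InvalidInputError("baseline_c25 must be >= 0")
    ph = phys.at(0.0) if isinstance(phys, PhysiologyPlan) else phys
    wt = ph.total_volume
    clmax_t = p.clmax * (wt / p.clmax_wt_ref) ** p.clmax_exponent
    cl25 = clearance_rate_constant(baseline_c25, clmax_t, p.c50, p.gamma)
    endog = cl25 * baseline_c25 * ph.v_ven / p.f_m

    q_l, cl_h = ph.q_liver, p.cl_h
    # vitamin D steady state: elimination flux == endog
    c_dart = endog * (q_l + cl_h) / (q_l * cl_h)
    c_dven = c_dart * (ph.q_liver + ph.q_rb) / ph.q_co
    c_dliv = p.kp_l * q_l * c_dart / (q_l + cl_h)
    c_drb = p.kp_rb * c_dart
    # 25(OH)D steady state
    c25 = baseline_c25
    c25liv = p.kp25_l * (c25 + p.f_m * endog / q_l)
    y = np.zeros(n_states(reduced, ph.split))
    if reduced:
        a_dtot = c_dven * ph.v_ven + c_dart * ph.v_art + c_drb * ph.v_rb
        y[1], y[2] = a_dtot, c_dliv * ph.v_liver
        y[3], y[4], y[5] = c25 * ph.v_art, c25 * ph.v_ven, c25liv * ph.v_liver
        if ph.split:
            y[6] = p.kp25_fm * c25 * ph.v_fm
            y[7] = p.kp25_lm * c25 * ph.v_lm
        else:
            y[6] = p.kp25_rb * c25 * ph.v_rb
    else:
        y[1], y[2] = c_dart * ph.v_art, c_dven * ph.v_ven
        y[3], y[4] = c_dliv * ph.v_liver, c_drb * ph.v_rb
        y[5], y[6], y[7] = c25 * ph.v_art, c25 * ph.v_ven, c25liv * ph.v_liver
        if ph.split:
            y[8] = p.kp25_fm * c25 * ph.v_fm
            y[9] = p.kp25_lm * c25 * ph.v_lm
        else:
            y[8] = p.kp25_rb * c25 * ph.v_rb
    if not np.all(np.isfinite(y)):
        raise CalibrationError("calibrated initial state is not finite")
    return endog, y


def _as_plan(phys) -> tuple[PhysiologyPlan | None, PhysiologySet | None]:
    if isinstance(phys, PhysiologyPlan):
        return phys, None
    if isinstance(phys, PhysiologySet):
        return None, phys
    raise ConfigurationError("phys must be a PhysiologySet or PhysiologyPlan")


def simulate_individual(
    p: PbpkParameters,
    phys: PhysiologySet | PhysiologyPlan,
    doses: Sequence[DoseEvent],
    obs_times: np.ndarray,
    reduced: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    y0: np.ndarray | None = None,
    backend: str = "reference",
    return_states: bool = False,
):
    """Integrate one child's PBPK system; returns venous 25(OH)D (nmol/L).

    Doses are applied as instantaneous GI-amount increments at their
    recorded times (event times are forced as integration breakpoints).
    ``y0`` defaults to the calibrated steady state consistent with a zero
    initial 25(OH)D baseline only if given; normally pass the state from
    :func:`calibrate_endogenous_input`.

    ``backend="reference"`` uses SciPy's stiff LSODA integrator segment by
    segment; ``backend="fast"`` uses the compiled L-stable TR-BDF2 scheme
    (reduced mode only) used throughout estimation and population
    simulation.
    """
    obs_times = np.asarray(obs_times, dtype=float)
    if obs_times.size and (np.any(np.diff(obs_times) < 0) or obs_times[0] < 0):
        raise InvalidInputError("obs_times must be sorted and >= 0")
    plan, fixed = _as_plan(phys)
    split = plan.split if plan is not None else fixed.split

    if y0 is None:
        _, y0 = calibrate_endogenous_input(0.0, p, phys, reduced=reduced)
    y0 = np.asarray(y0, dtype=float)
    if y0.size != n_states(reduced, split):
        raise InvalidInputError("y0 has the wrong length for this mode")

    if backend == "fast":
        if not reduced:
            raise ConfigurationError("the fast backend implements the reduced mode only")
        from ._fastsim import integrate_fast

        return integrate_fast(p, phys, doses, obs_times, y0, return_states=return_states)
    if backend != "reference":
        raise ConfigurationError(f"unknown backend {backend!r}")

    def phys_at(t):
        return plan.at(t) if plan is not None else fixed

    def wt_at(t):
        return plan.weight_at_hours(t) if plan is not None else fixed.total_volume

    if reduced:
        def rhs(t, y):
            return _reduced_rhs(y, t, p, phys_at(t), wt_at(t))
    else:
        def rhs(t, y):
            return derivatives(y, t, p, phys_at(t))

    dose_list = sorted(doses, key=lambda d: d.time_h)
    events = sorted(
        {d.time_h for d in dose_list} | set(obs_times.tolist()) | {0.0}
    )
    t_end = max(events[-1], obs_times[-1] if obs_times.size else 0.0)
    dose_at = {}
    for d in dose_list:
        dose_at[d.time_h] = dose_at.get(d.time_h, 0.0) + d.amount_nmol

    y = y0.copy()
    out = {}
    states = {}
    t_prev = 0.0
    if 0.0 in dose_at:
        y[0] += dose_at[0.0]
    if obs_times.size and obs_times[0] == 0.0:
        out[0.0] = _c25_from_state(y0, phys_at(0.0), reduced)
        states[0.0] = y0.copy()
    for t_next in events:
        if t_next <= t_prev:
            continue
        sol = solve_ivp(
            rhs, (t_prev, t_next), y, method="LSODA", rtol=rtol, atol=atol,
            dense_output=False,
        )
        if not sol.success:
            raise SolverError(
                f"LSODA failed on [{t_prev}, {t_next}]: {sol.message}; "
                f"nfev={sol.nfev}, last state={y}"
            )
        y = sol.y[:, -1]
        if t_next in dose_at:
            y = y.copy()
            y[0] += dose_at[t_next]
        if np.any(obs_times == t_next):
            out[t_next] = _c25_from_state(y, phys_at(t_next), reduced)
            states[t_next] = y.copy()
        t_prev = t_next
    conc = np.array([out[t] for t in obs_times])
    if return_states:
        return conc, states
    return conc


def _c25_from_state(y: np.ndarray, phys: PhysiologySet, reduced: bool) -> float:
    idx = 4 if reduced else 6
    return float(y[idx] / phys.v_ven)
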