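"""Body composition, compartment volumes/flows and time-varying weight.

The PBPK model lumps the body into arterial blood, venous blood, liver and
a "rest of body" pool of non-eliminating organs; for 25(OH)D the rest of
body can be split into fat mass and lean mass. All compartment volumes are
directly proportional to body weight (apparent density 1 kg/L), and blood
flows use the adult reference man's flow fractions scaled to a paediatric
cardiac output anchor of 273 L/h at 30 kg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_CONFIG, ModelConfig
from .errors import ConfigurationError, InfeasiblePhysiologyError, InvalidInputError

__all__ = [
    "BodyComposition",
    "PhysiologySet",
    "WeightTrajectory",
    "fat_mass_fraction",
    "body_composition",
    "weight_at",
    "build_physiology",
    "allometric_clmax",
    "mean_cardiac_output",
]

#: cubic polynomial giving percent fat mass as a function of BMI Z-score
_FFM_COEFFS = (28.61, 7.82, -0.91, 0.03)
_FFM_ZMAX = 6.19
_FFM_FLOOR = 0.05
_FFM_CAP = 0.49


def fat_mass_fraction(zbmi: float) -> float:
    """Fraction of body weight that is fat mass, from the BMI-for-age Z-score.

    A cubic in ZBMI (28.61 + 7.82 z - 0.91 z^2 + 0.03 z^3, in percent),
    floored at 0.05 and capped at 0.49 above z = 6.19. At z = 0 a child is
    expected to carry 28.61% fat mass.
    """
    z = float(zbmi)
    if not math.isfinite(z):
        raise InvalidInputError(f"zbmi must be finite, got {zbmi!r}")
    if z > _FFM_ZMAX:
        return _FFM_CAP
    a0, a1, a2, a3 = _FFM_COEFFS
    pct = a0 + a1 * z + a2 * z * z + a3 * z ** 3
    return max(pct / 100.0, _FFM_FLOOR)


@dataclass(frozen=True)
class BodyComposition:
    """Weight split into fat mass and lean mass (blood and liver removed).

    ``lean_mass`` excludes blood and liver so that
    fat + lean + blood + liver = weight (1 kg/L density).
    """

    weight: float
    zbmi: float
    f_fm: float
    fat_mass: float
    lean_mass: float


def body_composition(
    weight: float, zbmi: float, config: ModelConfig = DEFAULT_CONFIG
) -> BodyComposition:
    """Fat/lean split of body weight for a child of given weight and ZBMI."""
    if weight <= 0:
        raise InvalidInputError(f"weight must be positive, got {weight}")
    f = fat_mass_fraction(zbmi)
    fat = f * weight
    blood_liver = (config.frac_arterial + config.frac_venous + config.frac_liver) * weight
    lean = weight - fat - blood_liver * config.density
    if lean <= 0:
        raise InfeasiblePhysiologyError(
            f"lean mass {lean:.3g} kg <= 0 for weight {weight} kg, zbmi {zbmi}"
        )
    return BodyComposition(weight=weight, zbmi=zbmi, f_fm=f, fat_mass=fat, lean_mass=lean)


@dataclass(frozen=True)
class WeightTrajectory:
    """Body weight as a function of time since baseline.

    Modes:
      * ``fixed`` — weight stays at ``wt0``;
      * ``population_linear`` — sex-specific population growth slope
        (3.08 kg/year boys, 3.23 kg/year girls by default);
      * ``individual_interpolated`` — linear interpolation between the
        child's recorded baseline and 3-year weights, extrapolated
        linearly beyond 3 years.
    """

    mode: str = "fixed"
    wt0: float = 30.0
    wt_final: float | None = None
    sex: str = "boy"
    slope: float | None = None  # kg/year; overrides the sex default

    def __post_init__(self):
        if self.mode not in ("fixed", "population_linear", "individual_interpolated"):
            raise ConfigurationError(f"unknown weight mode {self.mode!r}")
        if self.wt0 <= 0:
            raise InvalidInputError(f"wt0 must be positive, got {self.wt0}")
        if self.mode == "individual_interpolated" and self.wt_final is None:
            raise ConfigurationError("individual_interpolated mode requires wt_final")

    def slope_per_year(self, config: ModelConfig = DEFAULT_CONFIG) -> float:
        """The linear growth rate in kg/year implied by the trajectory."""
        if self.mode == "fixed":
            return 0.0
        if self.mode == "population_linear":
            if self.slope is not None:
                return self.slope
            return (
                config.weight_slope_girl if self.sex == "girl" else config.weight_slope_boy
            )
        return (self.wt_final - self.wt0) / 3.0


def weight_at(
    traj: WeightTrajectory, t: float, config: ModelConfig = DEFAULT_CONFIG
) -> float:
    """Weight (kg) at time ``t`` years after baseline (linear beyond 3 y)."""
    if t < 0:
        raise InvalidInputError(f"t must be >= 0, got {t}")
    return traj.wt0 + traj.slope_per_year(config) * t


@dataclass(frozen=True)
class PhysiologySet:
    """Compartment volumes (L) and blood flows (L/h) for one individual.

    ``v_rb`` is the rest-of-body volume (all non-eliminating organs); for
    the fat/lean split used by the final 25(OH)D model it decomposes as
    ``v_rb = v_fm + v_lm``. Flow conservation holds: q_liver + q_rb = q_co,
    and the rest-of-body flow splits between fat and lean mass in
    proportion to their volumes.
    """

    v_art: float
    v_ven: float
    v_liver: float
    v_rb: float
    v_fm: float
    v_lm: float
    q_co: float
    q_liver: float
    q_rb: float
    split: bool

    @property
    def q_fm(self) -> float:
        return self.q_rb * self.v_fm / (self.v_fm + self.v_lm) if self.split else 0.0

    @property
    def q_lm(self) -> float:
        return self.q_rb - self.q_fm if self.split else 0.0

    @property
    def total_volume(self) -> float:
        return self.v_art + self.v_ven + self.v_liver + self.v_rb


def build_physiology(
    weight: float,
    zbmi: float = 0.0,
    variant_split: bool = True,
    config: ModelConfig = DEFAULT_CONFIG,
) -> PhysiologySet:
    """Compartment volumes and flows for a child of given weight and ZBMI.

    Volumes are weight-proportional (a 30 kg child: 0.6 L arterial, 1.80 L
    venous, 0.77 L liver); cardiac output scales linearly from 273 L/h at
    30 kg; the liver receives a configurable fraction (default 0.255) of
    cardiac output.
    """
    if weight <= 0:
        raise InvalidInputError(f"weight must be positive, got {weight}")
    c = config
    v_art = c.frac_arterial * weight
    v_ven = c.frac_venous * weight
    v_liver = c.frac_liver * weight
    v_rb = weight / c.density - v_art - v_ven - v_liver
    if v_rb <= 0:
        raise InfeasiblePhysiologyError(f"rest-of-body volume <= 0 at weight {weight}")
    if variant_split:
        comp = body_composition(weight, zbmi, c)
        v_fm, v_lm = comp.fat_mass / c.density, comp.lean_mass / c.density
    else:
        v_fm = v_lm = 0.0
    q_co = c.cardiac_output_ref * weight / c.weight_ref
    q_liver = c.liver_flow_fraction * q_co
    q_rb = q_co - q_liver
    return PhysiologySet(
        v_art=v_art,
        v_ven=v_ven,
        v_liver=v_liver,
        v_rb=v_rb,
        v_fm=v_fm,
        v_lm=v_lm,
        q_co=q_co,
        q_liver=q_liver,
        q_rb=q_rb,
        split=bool(variant_split),
    )


def allometric_clmax(clmax_ref: float, wt: float, wt_ref: float) -> float:
    """Scale a maximal 25(OH)D clearance rate constant by weight^0.75.

    clmax(wt) = clmax_ref * (wt / wt_ref)^0.75 — e.g. a 30 kg child's
    0.0119 1/h extrapolates to 0.0225 1/h at 70 kg.
    """
    if clmax_ref <= 0 or wt <= 0 or wt_ref <= 0:
        raise InvalidInputError("clmax_ref, wt and wt_ref must all be positive")
    return clmax_ref * (wt / wt_ref) ** 0.75


def mean_cardiac_output(q_boys: float, q_girls: float) -> float:
    """Average of boy/girl cardiac outputs in L/min, returned in L/h."""
    if q_boys <= 0 or q_girls <= 0:
        raise InvalidInputError("cardiac outputs must be positive")
    return (q_boys + q_girls) / 2.0 * 60.0
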