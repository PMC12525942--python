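"""Model configuration: physiological constants and structural PK defaults.

Everything a user might legitimately retune lives here rather than being
hard-coded: compartment volume fractions, the liver blood-flow fraction,
the reference cardiac output, default weight-gain slopes, and the
structural parameters inherited from the adult vitamin D model lineage
(hepatic clearance, absorption rate, partition coefficients, C50, gamma).

Units: volumes L, flows L/h, weights kg, rate constants 1/h,
concentrations nmol/L, amounts nmol, doses at the interface in ug.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

#: molar mass of vitamin D3 (cholecalciferol), g/mol
MOLAR_MASS_D3 = 384.64

HOURS_PER_YEAR = 365.25 * 24.0
HOURS_PER_WEEK = 168.0


def ug_to_nmol(ug: float) -> float:
    """Convert a vitamin D3 dose from micrograms to nanomoles (250 ug -> 650 nmol)."""
    return ug * 1000.0 / MOLAR_MASS_D3


@dataclass(frozen=True)
class ModelConfig:
    """Physiological and structural constants shared by all model variants.

    Volume fractions are chosen so that a 30 kg child has 0.6 L arterial
    blood, 1.80 L venous blood and a 0.77 L liver; the apparent tissue
    density is 1 kg/L, so compartment volumes sum to body weight.
    """

    # --- physiology ---
    frac_arterial: float = 0.02        # fraction of body weight
    frac_venous: float = 0.06
    frac_liver: float = 0.0257
    density: float = 1.0               # kg/L
    liver_flow_fraction: float = 0.255  # fraction of cardiac output to the liver
    cardiac_output_ref: float = 273.0  # L/h at the reference weight
    weight_ref: float = 30.0           # kg; allometric + flow reference
    allometric_exponent: float = 0.75
    weight_slope_boy: float = 3.08     # kg/year, population linear growth
    weight_slope_girl: float = 3.23

    # --- structural PK (adult-lineage defaults, configurable) ---
    f_m: float = 0.33                  # fraction of vitamin D converted to 25(OH)D
    cl_h: float = 20.0                 # hepatic vitamin D clearance, L/h
    ka: float = 0.25                   # GI absorption rate constant, 1/h
    kp_rb: float = 0.5                 # vitamin D rest-of-body partition coefficient
    kp_l: float = 1.0                  # vitamin D liver partition coefficient
    kp25_l: float = 1.0                # 25(OH)D liver partition coefficient (fixed)
    kp25_fm: float = 4.66              # 25(OH)D fat-mass partition coefficient
    kp25_lm: float = 4.0               # 25(OH)D lean-mass partition coefficient
    kp25_rb: float = 4.48              # 25(OH)D rest-of-body Kp (non-split variants)
    c50: float = 30.0                  # nmol/L, 25(OH)D at half-maximal clearance
    gamma: float = 1.0                 # sigmoidicity of the clearance function

    def replace(self, **kwargs) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            from .errors import ConfigurationError

            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


DEFAULT_CONFIG = ModelConfig()
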