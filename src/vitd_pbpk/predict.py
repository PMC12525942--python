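"""Individual prediction helpers shared by estimation and simulation.

``predict_child`` runs the full per-child pipeline: map population
parameters + random effects to the individual, calibrate the endogenous
input against the child's baseline 25(OH)D, and integrate over the
child's dosing record.

``EtaGridInterpolator`` precomputes predictions on a grid of the single
CLmax random effect and interpolates them cubically; Monte Carlo loops
(NPDE, VPC, per-child prediction intervals) draw thousands of eta
realisations per child, and each trajectory depends on eta through one
smooth scalar, so interpolation replaces an ODE solve per draw at
negligible error (validated in the test suite).
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

from .pbpk import calibrate_endogenous_input, simulate_individual
from .population import PopulationModel, individual_parameters, physiology_plan
from .records import ChildRecord

__all__ = ["predict_child", "EtaGridInterpolator"]


def predict_child(
    pop: PopulationModel,
    cov: ChildRecord,
    eta: dict[str, float] | None = None,
    times_h: np.ndarray | None = None,
    backend: str = "fast",
    baseline_c25: float | None = None,
    doses=None,
) -> np.ndarray:
    """Model-predicted venous 25(OH)D (nmol/L) for one child.

    eta = None gives the population prediction (random effects at zero).
    Defaults to the child's observation times and recorded doses; pass
    ``times_h`` for a custom output grid and ``doses`` to impose a
    regimen (e.g. a virtual daily schedule). ``baseline_c25`` overrides
    the calibration anchor.
    """
    times = cov.obs_times_h if times_h is None else np.asarray(times_h, dtype=float)
    p = individual_parameters(pop, eta, cov)
    plan = physiology_plan(pop, cov)
    base = cov.baseline_c25 if baseline_c25 is None else baseline_c25
    endog, y0 = calibrate_endogenous_input(base, p, plan, reduced=True)
    p = p.replace(endog=endog)
    dose_list = cov.doses if doses is None else doses
    return simulate_individual(
        p, plan, dose_list, times, reduced=True, y0=y0, backend=backend
    )


class EtaGridInterpolator:
    """Cubic interpolation of per-child predictions over the CLmax eta.

    Supports models whose only random effect is on CLmax (the final
    model). Nodes span ``span`` prior standard deviations (default 4.5)
    plus a small margin, clipped to at least [-1.5, 1.5] in eta units.
    """

    def __init__(
        self,
        pop: PopulationModel,
        cov: ChildRecord,
        times_h: np.ndarray | None = None,
        n_nodes: int = 15,
        span: float = 4.5,
        backend: str = "fast",
        doses=None,
    ):
        if set(pop.variant.random_effects) - {"clmax"}:
            raise NotImplementedError(
                "eta-grid interpolation supports a single CLmax random effect; "
                "use direct simulation for multi-eta variants"
            )
        self.times_h = (
            cov.obs_times_h if times_h is None else np.asarray(times_h, dtype=float)
        )
        sd = float(np.sqrt(pop.omega.get("clmax", 0.0)))
        half = max(span * sd * 1.05, 1.5)
        self.nodes = np.linspace(-half, half, n_nodes)
        preds = np.empty((n_nodes, self.times_h.size))
        for i, e in enumerate(self.nodes):
            preds[i] = predict_child(
                pop, cov, {"clmax": float(e)}, self.times_h, backend=backend,
                doses=doses,
            )
        self._spline = CubicSpline(self.nodes, preds, axis=0)
        self._lo, self._hi = self.nodes[0], self.nodes[-1]

    def __call__(self, eta_clmax) -> np.ndarray:
        """Predictions at one eta or a vector of etas (clipped to the grid)."""
        e = np.clip(np.asarray(eta_clmax, dtype=float), self._lo, self._hi)
        return self._spline(e)
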