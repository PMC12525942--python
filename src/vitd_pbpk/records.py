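"""Per-child record: covariates, dosing events and observations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .pbpk import DoseEvent

__all__ = ["ChildRecord"]


@dataclass
class ChildRecord:
    """Covariates plus event history for one subject.

    The baseline 25(OH)D (``baseline_c25``) anchors the endogenous-input
    calibration; it is normally the pre-dose observation at time 0.
    Times are hours since the child's baseline visit.
    """

    id: int | str
    sex: str = "boy"
    age: float = 9.0
    wt0: float = 30.0
    wt_final: float | None = None
    zbmi: float = 0.0
    baseline_c25: float = 64.7
    dose_times_h: np.ndarray = field(default_factory=lambda: np.empty(0))
    dose_amounts_ug: np.ndarray = field(default_factory=lambda: np.empty(0))
    obs_times_h: np.ndarray = field(default_factory=lambda: np.empty(0))
    obs_dv: np.ndarray = field(default_factory=lambda: np.empty(0))
    lloq_flags: np.ndarray | None = None

    def __post_init__(self):
        self.dose_times_h = np.asarray(self.dose_times_h, dtype=float)
        self.dose_amounts_ug = np.asarray(self.dose_amounts_ug, dtype=float)
        self.obs_times_h = np.asarray(self.obs_times_h, dtype=float)
        self.obs_dv = np.asarray(self.obs_dv, dtype=float)
        if self.dose_times_h.size != self.dose_amounts_ug.size:
            raise DataError(f"child {self.id}: dose times/amounts length mismatch")
        if self.obs_times_h.size != self.obs_dv.size:
            raise DataError(f"child {self.id}: observation times/values length mismatch")
        if self.lloq_flags is None:
            self.lloq_flags = np.zeros(self.obs_times_h.size, dtype=bool)
        else:
            self.lloq_flags = np.asarray(self.lloq_flags, dtype=bool)

    @property
    def doses(self) -> list[DoseEvent]:
        return [
            DoseEvent(t, a) for t, a in zip(self.dose_times_h, self.dose_amounts_ug)
        ]

    @property
    def n_obs(self) -> int:
        return int(self.obs_times_h.size)

    def fit_mask(self) -> np.ndarray:
        """Observations entering the residual likelihood.

        The time-0 baseline sample is the calibration anchor (excluded);
        below-LLOQ samples are excluded with their flag preserved.
        """
        return (self.obs_times_h > 0) & ~self.lloq_flags
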