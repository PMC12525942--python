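"""Exception hierarchy for vitd_pbpk."""


class VitdPbpkError(Exception):
    """Base class for all package errors."""


class InvalidInputError(VitdPbpkError, ValueError):
    """A scalar argument is outside its physical/mathematical domain."""


class ConfigurationError(VitdPbpkError, ValueError):
    """A model/physiology configuration is inconsistent or incomplete."""


class InfeasiblePhysiologyError(VitdPbpkError, ValueError):
    """Covariates imply a non-physical body composition (e.g. lean mass <= 0)."""


class CalibrationError(VitdPbpkError, RuntimeError):
    """Endogenous-input calibration could not balance the model."""


class SolverError(VitdPbpkError, RuntimeError):
    """The ODE/DAE integrator failed; message carries step diagnostics."""


class DataError(VitdPbpkError, ValueError):
    """An input dataset is malformed (names the offending child/field/rows)."""


class SchemaError(DataError):
    """An event table violates the documented CSV dialect."""
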