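"""Exception hierarchy for the gaitspec pipeline."""


class GaitspecError(Exception):
    """Base class for all package errors."""


class ParameterError(GaitspecError, ValueError):
    """An argument violates a documented precondition."""


class StructuralError(GaitspecError, ValueError):
    """Input data is malformed (length mismatch, empty window, ...)."""


class InsufficientDataError(GaitspecError, ValueError):
    """Series too short for even a single analysis window."""


class NoCadencePeakError(GaitspecError, RuntimeError):
    """No finite spectral magnitude inside the cadence search range."""


class DegenerateSpectrumError(GaitspecError, RuntimeError):
    """Average spectrum has zero magnitude at the cadence; cannot scale."""


class DegenerateBasisError(GaitspecError, ValueError):
    """Basis matrix is numerically rank deficient."""


class JoinError(GaitspecError, KeyError):
    """Subject identifiers do not match across input tables."""


class RankError(GaitspecError, RuntimeError):
    """Unpenalized normal equations are singular (e.g. lambda = 0, p > N)."""


class ConvergenceError(GaitspecError, RuntimeError):
    """Variance-component optimization failed to converge."""


class ConfigError(GaitspecError, ValueError):
    """Configuration file contains unknown keys or invalid values."""
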