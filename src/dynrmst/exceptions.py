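"""Exception hierarchy for dynrmst.

All package-specific errors derive from :class:`DynRmstError` so callers can
catch everything with one clause while still distinguishing input problems
(`FormatError`, `ValidationError`, `ConfigError`) from numerical/statistical
failures (`FitError`, `LikelihoodError`, `InferenceError`, `EstimationError`).
"""


class DynRmstError(Exception):
    """Base class for all dynrmst errors."""


class FormatError(DynRmstError, ValueError):
    """Input file/table does not have the expected structure."""


class ValidationError(DynRmstError, ValueError):
    """Data violates the subject-level survival-data contract."""


class ConfigError(DynRmstError, ValueError):
    """Invalid run configuration (grids, preset names, levels...)."""


class EstimationError(DynRmstError, RuntimeError):
    """A nonparametric estimate cannot be formed (e.g. no events)."""


class LikelihoodError(DynRmstError, RuntimeError):
    """The censored-data log-likelihood is not finite for the given data."""


class FitError(DynRmstError, RuntimeError):
    """Maximum-likelihood fitting failed across all starts."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class InferenceError(DynRmstError, RuntimeError):
    """Variance/CI computation is unavailable (e.g. singular information)."""


class DiagnosticError(DynRmstError, RuntimeError):
    """A diagnostic summary cannot be computed from the given curve."""
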