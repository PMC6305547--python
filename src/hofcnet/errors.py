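"""Exception hierarchy shared across the package."""


class HofcnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HofcnetError, ValueError):
    """A delimited input file violates the expected layout (ragged rows, wrong shape, ...)."""


class DegenerateSignalError(HofcnetError, ValueError):
    """A time-series column is constant, so correlation-type estimators are undefined."""


class WindowError(HofcnetError, ValueError):
    """A sliding-window specification is incompatible with the series length."""


class AsymmetricMatrixError(HofcnetError, ValueError):
    """A matrix required to be symmetric exceeds the symmetry tolerance."""


class SingularMatrixError(HofcnetError, ValueError):
    """A matrix stayed numerically singular even after the jitter escalation."""


class DegenerateInputError(HofcnetError, ValueError):
    """Input carries no usable variation (e.g. all windowed networks identical)."""


class UndefinedMetricError(HofcnetError, ValueError):
    """A confusion-matrix metric is undefined (empty positive or negative class)."""


class ConfigError(HofcnetError, ValueError):
    """A run configuration is missing keys or violates an invariant."""


class SpecError(HofcnetError, ValueError):
    """A synthetic-data specification cannot produce a valid (positive definite) model."""
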