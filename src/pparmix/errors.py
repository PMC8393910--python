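"""Exception hierarchy for the reporter-assay pipeline."""


class PparmixError(Exception):
    """Base class for all pipeline errors."""


class InvalidDesignError(PparmixError, ValueError):
    """A dose series, mixture or plate design violates its preconditions."""


class DegenerateWellError(PparmixError, ValueError):
    """A well cannot be normalized (non-positive control-reporter signal)."""


class MissingControlError(PparmixError, ValueError):
    """A plate has no vehicle wells to normalize against."""


class FitError(PparmixError, ValueError):
    """A model fit is impossible (rank deficiency, non-finite coefficients)."""


class ConfigError(PparmixError, ValueError):
    """A run configuration is invalid; message carries the field path."""
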