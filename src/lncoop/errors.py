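"""Exception hierarchy shared across the pipeline."""


class LncoopError(Exception):
    """Base class for all pipeline errors."""


class ParseError(LncoopError):
    """A file could not be parsed; message carries row/column coordinates."""


class ValidationError(LncoopError):
    """Parsed content violates a declared constraint (range, uniqueness...)."""


class AlignmentError(LncoopError):
    """Matrices share no samples and cannot form a bundle."""


class ConfigurationError(LncoopError):
    """A simulation or analysis configuration is internally inconsistent."""


class DegenerateFitError(LncoopError):
    """A model fit is undefined (constant covariate, rank deficiency, no events)."""
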