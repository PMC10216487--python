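"""Exception hierarchy shared across the package."""


class FitscreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(FitscreenError, ValueError):
    """A configuration object violates its invariants."""


class InputError(FitscreenError, ValueError):
    """Runtime inputs to an operation are malformed or inconsistent."""


class ParseError(FitscreenError, ValueError):
    """A table row or file could not be interpreted."""


class QueryLookupError(FitscreenError, KeyError):
    """A requested gene or identifier is absent from the data."""


class DegenerateCurveError(FitscreenError, ValueError):
    """The ranked-coefficient curve has no detectable elbow."""
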