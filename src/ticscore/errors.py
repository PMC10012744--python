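"""Exception hierarchy shared across the package."""


class TicsError(Exception):
    """Base class for all package errors."""


class ParseError(TicsError):
    """Malformed input file (GMT, TSV, config)."""


class DegenerateDataError(TicsError):
    """Input is structurally valid but statistically unusable
    (all-identical scores, one-class outcome, no comparable pairs...)."""


class CollinearityError(TicsError):
    """Constant or exactly collinear covariate columns in a model fit."""


class SeparationError(TicsError):
    """Monotone partial likelihood: a covariate perfectly separates events."""


class FitError(TicsError):
    """Model fit failed to converge or produced a singular information matrix."""
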