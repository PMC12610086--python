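"""Exception hierarchy shared across the package."""


class TrophipathError(Exception):
    """Base class for all package errors."""


class ValidationError(TrophipathError):
    """An annotation object violates a structural invariant."""


class ParameterError(TrophipathError):
    """A caller-supplied parameter is outside its valid range."""


class UndefinedMetricError(TrophipathError):
    """A metric's denominator is zero (e.g. specificity with tn+fp=0)."""
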