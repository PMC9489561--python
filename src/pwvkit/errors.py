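"""Exception hierarchy.

All package errors derive from :class:`PwvError` so callers can catch one type.
"""


class PwvError(Exception):
    """Base class for all pwvkit errors."""


class ParameterError(PwvError, ValueError):
    """Invalid parameter or violated type invariant."""


class ConstructionError(PwvError):
    """Unphysical construction, e.g. a transit delay at least one cardiac cycle long."""


class AnalysisError(PwvError):
    """Curve analysis cannot proceed, e.g. a flat curve with no upslope."""


class UndefinedPWVError(AnalysisError):
    """Transit time is zero, so distance / time is undefined."""


class FormatError(PwvError, ValueError):
    """Malformed input file."""
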