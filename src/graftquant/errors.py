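"""Exception types shared across the package."""


class GraftQuantError(ValueError):
    """Base class for all validation errors raised by graftquant."""


class ParameterError(GraftQuantError):
    """A simulation or detection parameter violates its invariants."""


class InputError(GraftQuantError):
    """Malformed input data (file contents, array shapes, labels)."""


class GeometryError(GraftQuantError):
    """Mask geometry does not support the requested operation."""


class DegenerateBaselineError(GraftQuantError):
    """The fluorescence baseline F0 is non-positive at some frame."""
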