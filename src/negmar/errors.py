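"""Exception types shared across the package."""


class NegmarError(Exception):
    """Base class for all package errors."""


class GeometryError(NegmarError, ValueError):
    """Array shape or scan-geometry parameters are inconsistent."""


class NonFiniteError(NegmarError, ValueError):
    """Input array contains NaN or infinity."""


class GenerationError(NegmarError, RuntimeError):
    """A synthetic case failed one of its generation-time assertions."""
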