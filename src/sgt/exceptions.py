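"""Exception hierarchy.

All package errors derive from :class:`SGTError` so callers (and the CLI)
can distinguish domain failures from genuine I/O or programming errors.
"""


class SGTError(Exception):
    """Base class for all errors raised by this package."""


class UsageError(SGTError, ValueError):
    """A caller-supplied option or argument is invalid (bad threshold, unit, mode)."""


class ParseError(SGTError, ValueError):
    """An input file could not be parsed; the message names the offending line."""


class ValidationError(SGTError, ValueError):
    """Parsed data violate a structural invariant (duplicate wells, bad time grid)."""


class DesignError(ValidationError):
    """An assay design references wells or samples the plate does not provide."""


class FitError(SGTError, ValueError):
    """A regression could not be fitted (too few points, degenerate predictor)."""


class ModelSanityError(FitError):
    """A fitted model is unusable for inversion (e.g. non-negative calibration slope)."""


class EstimationError(SGTError, ValueError):
    """A derived quantity (doubling time, concentration) could not be estimated."""


class RangeError(SGTError, ValueError):
    """A prediction was requested outside the fitted range without opting in."""
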