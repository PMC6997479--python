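"""Exception hierarchy.

All renoquant errors derive from :class:`RenoquantError`; most also derive
from ``ValueError`` so that callers validating inputs can catch either.
"""


class RenoquantError(Exception):
    """Base class for all renoquant errors."""


class InputError(RenoquantError, ValueError):
    """Malformed or inconsistent input data (schedules, masks, curves)."""


class ParameterError(RenoquantError, ValueError):
    """Out-of-range model or algorithm parameter."""


class ConfigurationError(RenoquantError, ValueError):
    """Phantom or study configuration that cannot be realized (e.g. kidney
    volumes that do not fit on the voxel grid)."""


class FitError(RenoquantError, ValueError):
    """Regression could not be performed (too few usable points)."""


class UndefinedSRFError(RenoquantError, ValueError):
    """Split renal function is undefined because the combined functional
    signal of the two kidneys is non-positive (a non-functioning pair)."""


class EvaluationError(RenoquantError, ValueError):
    """A drainage or agreement metric is undefined for the given curve or
    table (zero reference activity, degenerate table, constant vector)."""
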