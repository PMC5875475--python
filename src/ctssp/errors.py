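"""Exception hierarchy.

Two branches so the CLI can map failures onto distinct exit codes:
``InputError`` (bad files, configs, geometry) and ``ComputationError``
(degenerate signals, failed fits, truncated profiles).
"""


class SSPError(Exception):
    """Base class for all package errors."""


class InputError(SSPError):
    """Invalid or unreadable input (files, directories, configs)."""


class AmbiguityError(InputError):
    """Input is readable but ambiguous (e.g. mixed series UIDs)."""


class SpacingError(InputError):
    """Slice spacing is non-uniform beyond tolerance."""


class BoundsError(InputError):
    """ROI (partially) outside the image bounds."""


class ConfigError(InputError):
    """Invalid configuration value or missing required field."""


class ComputationError(SSPError):
    """A well-formed input produced an unusable result."""


class DegenerateSignalError(ComputationError):
    """Signal has no usable peak (non-positive maximum, constant data)."""


class TruncatedProfileError(ComputationError):
    """Profile peak sits at an endpoint; the scan range missed the tails."""


class CrossingRangeError(ComputationError):
    """No half-maximum crossing found on one side of the curve."""


class FitError(ComputationError):
    """Nonlinear fit failed to converge."""


class DegenerateVarianceError(ComputationError):
    """Zero variance where a z statistic requires spread."""
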