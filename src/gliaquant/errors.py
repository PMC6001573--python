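"""Exception types shared across the package."""


class GliaquantError(Exception):
    """Base class for all package errors."""


class SizingError(GliaquantError):
    """Image too small to place the requested number of cells without overlap."""


class ProtocolMismatchError(GliaquantError):
    """Sweep traces inconsistent with the voltage-step protocol."""


class GridMismatchError(GliaquantError):
    """Two I/V curves do not share a voltage grid."""


class NoReversalError(GliaquantError):
    """An I/V curve has no sign change, so no reversal potential exists."""


class InsufficientBaselineError(GliaquantError):
    """Too little event-free baseline to estimate the noise SD."""


class InvalidShapeError(GliaquantError):
    """A cell mask is degenerate (empty, zero perimeter, or below minimum area)."""


class UndefinedMetricError(GliaquantError):
    """A metric is undefined for the given input (e.g. track too short)."""


class InvalidQCError(GliaquantError):
    """Quality-control input is invalid (e.g. nonpositive series resistance)."""


class DesignError(GliaquantError):
    """Statistical design does not match the supplied data."""
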