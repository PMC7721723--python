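"""Exception hierarchy.

All package-specific failures derive from :class:`AirwayKitError` so callers
can catch one base class; each subclass also derives from the closest builtin
(ValueError / RuntimeError) for idiomatic handling.
"""


class AirwayKitError(Exception):
    """Base class for all airwaykit errors."""


class ParameterError(AirwayKitError, ValueError):
    """Invalid parameter value (non-positive dimension, bad fraction, ...)."""


class FormatError(AirwayKitError, ValueError):
    """Unreadable or inconsistent image / table file."""


class GenerationError(AirwayKitError, RuntimeError):
    """A phantom could not be generated consistently (e.g. landmark outside mask)."""


class SegmentationError(AirwayKitError, RuntimeError):
    """Seed point not inside any above-threshold component."""


class CenterlinePathError(AirwayKitError, RuntimeError):
    """No skeleton path between the requested endpoints."""


class StationRangeError(AirwayKitError, ValueError):
    """Requested arclength station outside the centerline range."""


class OrderingError(AirwayKitError, ValueError):
    """Landmarks or stations supplied in an anatomically impossible order."""


class TopologyError(AirwayKitError, RuntimeError):
    """Inlet and outlet are not connected through the mask."""


class SolverError(AirwayKitError, RuntimeError):
    """Flow solver failed to converge within the iteration budget."""


class EmptySummaryError(AirwayKitError, RuntimeError):
    """No retained breaths to summarize."""


class InputError(AirwayKitError, ValueError):
    """Malformed sample input (e.g. fewer than two observations)."""
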