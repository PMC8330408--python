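"""Exception hierarchy.

Every error raised by swallowkit derives from :class:`SwallowKitError`, so
callers can catch the package's failures without masking programming errors.
"""


class SwallowKitError(Exception):
    """Base class for all swallowkit errors."""


class ConfigurationError(SwallowKitError):
    """Invalid configuration value (fps <= 0, family size < 1, unknown item...)."""


class InputValidationError(SwallowKitError):
    """Malformed input data: schema violations, non-finite coordinates,
    invariant-breaking annotations."""


class EventOrderError(SwallowKitError):
    """An interval's end event precedes its start event."""

    def __init__(self, start_name: str, end_name: str, start: int, end: int):
        self.start_name, self.end_name = start_name, end_name
        super().__init__(
            f"event '{end_name}' (frame {end}) precedes event "
            f"'{start_name}' (frame {start})"
        )


class GeometryError(SwallowKitError):
    """Degenerate geometry, e.g. coincident C2/C4 spine landmarks."""


class UndefinedStatisticError(SwallowKitError):
    """A statistic requested on input where it is undefined (empty vectors,
    degenerate contingency margins, too few pairs)."""


class SingularDesignError(SwallowKitError):
    """Rank-deficient regression design matrix."""


class SeparationError(SwallowKitError):
    """Complete separation in a logistic fit; a penalized fit may help but is
    never applied silently."""


class SynthesisError(SwallowKitError):
    """A true parameter value cannot be realized as an annotation."""


class ConsensusError(SwallowKitError):
    """Consensus requested while flagged discrepancies remain unresolved."""

    def __init__(self, pending):
        self.pending = list(pending)
        super().__init__(f"unresolved flagged items: {', '.join(self.pending)}")
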