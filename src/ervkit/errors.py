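"""Exception hierarchy shared across the package."""


class ErvkitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ErvkitError):
    """Malformed sequence input (bad characters, duplicate ids, empty file)."""


class AlignmentError(ErvkitError):
    """Records that should form an alignment do not (ragged lengths, empty)."""


class EmptyAlignmentError(AlignmentError):
    """A filtering step removed every column."""


class UndefinedDistanceError(ErvkitError):
    """No comparable sites remain between a pair of sequences."""


class SaturationError(ErvkitError):
    """Substitution proportions outside the domain of the distance correction."""

    def __init__(self, p: float, q: float):
        self.p = p
        self.q = q
        super().__init__(
            f"K2P correction undefined: P={p:.4f}, Q={q:.4f} "
            f"(requires 1-2P-Q > 0 and 1-2Q > 0)"
        )


class NotAProvirusError(ErvkitError):
    """No qualifying terminal repeat pair was found."""


class FlankError(ErvkitError):
    """Insufficient host flank for the requested operation."""


class SimulationError(ErvkitError):
    """Infeasible simulator constraints."""
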