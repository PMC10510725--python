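"""Exception hierarchy for cpgsilence."""


class CpgSilenceError(Exception):
    """Base class for all cpgsilence errors."""


class InvalidAlphabetError(CpgSilenceError):
    """Sequence contains a character outside {A, C, G, T}."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position  # 1-based
        super().__init__(
            f"invalid character {char!r} at position {position} "
            "(only A, C, G, T allowed)"
        )


class DinucleotideMismatchError(CpgSilenceError):
    """The dinucleotide at the requested position does not match the edit mode."""

    def __init__(self, position: int, expected: str, found: str):
        self.position = position
        self.expected = expected
        self.found = found
        super().__init__(
            f"expected {expected!r} at position {position}, found {found!r}"
        )


class UnreachableTargetError(CpgSilenceError):
    """Density-lowering edits exhausted without reaching the target density."""

    def __init__(self, target: float, achieved: float):
        self.target = target
        self.achieved = achieved
        super().__init__(
            f"target density {target:.3f}% unreachable with the given "
            f"strategy; achieved {achieved:.3f}%"
        )


class InsufficientEventsError(CpgSilenceError):
    """Too few flow-cytometry events to fit the control distribution."""


class DegenerateDistributionError(CpgSilenceError):
    """Control events have zero spread; the log-normal fit is undefined."""


class UndefinedNormalizationError(CpgSilenceError):
    """Background silenced fraction is 1; nothing is available for silencing."""


class InsufficientPointsError(CpgSilenceError):
    """Fewer than two usable timepoints remain for the switching-rate fit."""


class DegenerateComparisonError(CpgSilenceError):
    """Both switching-rate fits have zero standard error; Wald z is undefined."""
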