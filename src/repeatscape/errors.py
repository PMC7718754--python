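"""Exception types shared across the package."""


class RepeatscapeError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(RepeatscapeError, ValueError):
    """An argument violates a documented precondition."""


class InfeasibleProfileError(InvalidArgumentError):
    """Requested repeat content does not fit into the genome."""


class InsufficientReadsError(RepeatscapeError):
    """Too few reads to assemble a consensus."""


class InsufficientDataError(RepeatscapeError):
    """Too few observations for a statistical estimate."""


class EmptyDistributionError(RepeatscapeError):
    """No read mapped to the target; dating refuses to proceed."""


class ImplausiblePairError(RepeatscapeError):
    """Two sequences are too divergent to be an LTR pair."""


class DesynchronizedPairsError(RepeatscapeError):
    """Paired FASTQ mates are out of sync."""


class ConfigError(RepeatscapeError):
    """One or more configuration problems, collected together."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in self.problems))


class MissingStageError(RepeatscapeError):
    """A pipeline stage was requested before its upstream stage ran."""
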