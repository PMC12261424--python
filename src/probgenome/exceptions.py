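"""Package-specific exception types."""


class ProbGenomeError(Exception):
    """Base class for errors raised by probgenome."""


class CoordinateMismatchError(ProbGenomeError):
    """A variant's reference allele disagrees with the backbone genome,
    typically indicating a coordinate-system or assembly mismatch."""


class FormatVersionError(ProbGenomeError):
    """An on-disk container carries an unknown or unsupported version tag."""


class InvalidWindowError(ProbGenomeError):
    """A requested genome window is out of range or degenerate."""


class UnusableRecordError(ProbGenomeError):
    """A variant record carries neither an allele-frequency field nor
    genotypes from which a frequency could be computed."""
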