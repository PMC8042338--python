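"""Exception hierarchy shared across the package."""


class MirsiteError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MirsiteError):
    """Malformed input file (empty FASTA record, missing column, ...)."""


class AlphabetError(MirsiteError):
    """A sequence contains characters outside the accepted RNA alphabet."""


class BoundaryError(MirsiteError):
    """Transcript region boundaries are inconsistent with the sequence."""


class FrameError(MirsiteError):
    """A declared CDS whose length is not a multiple of three."""


class ReferenceError_(MirsiteError):
    """An annotation row refers to a sequence id absent from the FASTA."""


class ContractError(MirsiteError):
    """An operation was called with arguments violating its contract."""


class ScanError(MirsiteError):
    """A transcript is too short to be scanned with the given miRNA."""


class CoordinateError(MirsiteError):
    """A cluster interval falls outside the segment it refers to."""


class GenerationError(MirsiteError):
    """The synthetic-data generator could not satisfy a planting target."""


class UndefinedCorrelationError(MirsiteError):
    """Correlation requested on a degenerate (zero-variance) input."""
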