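"""Exception hierarchy.

Every error raised by the pipeline orchestrator is prefixed with the name of
the processing stage that produced it, so failures in long multiverse runs
can be attributed without a traceback.
"""


class BrainTxError(Exception):
    """Base class for all package errors."""


class FileMissingError(BrainTxError, FileNotFoundError):
    """A required input file is absent from a donor directory."""


class FormatError(BrainTxError, ValueError):
    """An input file violates the expected dialect (shape, header, dtype)."""


class MetadataError(BrainTxError, ValueError):
    """Atlas labels and region metadata disagree."""


class ParameterError(BrainTxError, ValueError):
    """A numeric or categorical parameter is outside its allowed set."""


class MappingError(BrainTxError, ValueError):
    """A lookup table (coordinates, reannotation) does not cover its keys."""


class ConfigurationError(BrainTxError, ValueError):
    """A pipeline configuration is internally inconsistent or unsupported
    by the supplied data (e.g. RNAseq-based probe selection without RNAseq)."""


class DegenerateInputError(BrainTxError, ValueError):
    """An analysis input is degenerate (zero variance, too few regions)."""


class EmptyResultError(BrainTxError, ValueError):
    """A processing stage produced no usable output (e.g. no region received
    any tissue sample)."""


class IncompleteGridError(BrainTxError, ValueError):
    """The estimates table does not cover a full factorial of the grid."""
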