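"""Exception hierarchy shared across the pipeline."""


class ExactRnaError(Exception):
    """Base class for all pipeline errors."""


class FastaFormatError(ExactRnaError):
    """Malformed or invalid FASTA input."""


class FastqFormatError(ExactRnaError):
    """Malformed FASTQ record; carries the 0-based record index."""

    def __init__(self, message: str, record_index: int | None = None):
        super().__init__(message)
        self.record_index = record_index


class GeometryError(ExactRnaError):
    """Read length incompatible with the trim-and-split geometry."""


class AnnotationError(ExactRnaError):
    """Invalid gene annotation (out of bounds, duplicate ids, empty footprint)."""


class ConsistencyError(ExactRnaError):
    """Internally inconsistent inputs (labels, coordinates, missing genes)."""


class GroupingError(ExactRnaError):
    """A condition group is empty or a gene is absent from one condition."""


class ConfigError(ExactRnaError):
    """Invalid simulation or pipeline configuration."""
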