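"""Exception hierarchy shared across the pipeline stages."""


class MitocbeError(Exception):
    """Base class for all package errors."""


class FormatError(MitocbeError):
    """Malformed input file (FASTA/FASTQ/SAM) or illegal sequence alphabet."""


class CoordinateError(MitocbeError):
    """Position or interval outside the reference, or an illegal wrap on a linear reference."""


class GeometryError(MitocbeError):
    """TALE windows and spacer do not form a valid editor layout."""


class ConfigError(MitocbeError):
    """Invalid or incomplete pipeline/simulation configuration."""


class DataError(MitocbeError):
    """Input data inconsistent with the reference or with itself."""
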