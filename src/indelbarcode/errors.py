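"""Exception hierarchy shared across the pipeline."""


class IndelBarcodeError(Exception):
    """Base class for all package errors."""


class FormatError(IndelBarcodeError):
    """Malformed input file (empty, bad symbols, missing columns)."""


class AlignmentError(FormatError):
    """Sequences do not form a rectangular alignment."""


class ValidationError(IndelBarcodeError):
    """Metadata violates its invariants."""


class ConsistencyError(IndelBarcodeError):
    """Cross-object inconsistency (e.g. indel outside its alignment)."""


class DistanceUndefinedError(IndelBarcodeError):
    """A pair of sequences shares zero usable characters."""

    def __init__(self, id_a: str, id_b: str):
        self.pair = (id_a, id_b)
        super().__init__(
            f"p-distance undefined for pair ({id_a!r}, {id_b!r}): "
            "no usable characters shared"
        )


class InferenceError(IndelBarcodeError):
    """Tree inference cannot proceed (undefined distances, too many discarded replicates)."""


class ConfigError(IndelBarcodeError):
    """Invalid simulation or run configuration."""


class PipelineError(IndelBarcodeError):
    """Orchestration-level failure (e.g. empty id intersection across loci)."""
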