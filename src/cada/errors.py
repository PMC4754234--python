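"""Exception hierarchy for the pipeline."""


class CadaError(Exception):
    """Base class for all package errors."""


class FormatError(CadaError):
    """Unreadable or unsupported image file format."""


class DimensionalityError(CadaError):
    """Image is not a 3-D volume."""


class DegenerateInputError(CadaError):
    """Input is constant, zero-variance or otherwise degenerate."""


class SampleSizeError(CadaError):
    """Too few samples/voxels for the requested estimate."""


class InsufficientInputError(CadaError):
    """Fewer inputs than the operation requires (e.g. < 2 controls)."""


class EmptySegmentationError(CadaError):
    """Segmentation produced no high-uptake voxels for a hemisphere."""

    def __init__(self, side: str, message: str | None = None):
        self.side = side
        super().__init__(message or f"empty high-uptake segmentation on side {side!r}")


class EmptyROIError(CadaError):
    """A region of interest contains no voxels."""


class DegeneracyError(CadaError):
    """Point set is coplanar or otherwise unfit for ellipsoid fitting."""


class DomainError(CadaError):
    """Argument outside its mathematical domain (e.g. DI not in [0,1])."""


class ClassBalanceError(CadaError):
    """Classification input contains a single class."""


class JoinError(CadaError):
    """No overlapping subjects between feature and clinical tables."""


class ConfigError(CadaError):
    """Invalid pipeline configuration."""
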