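"""Exception types raised across the pipeline."""


class MicrocapError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(MicrocapError):
    """Invalid phantom geometry (negative dimensions, cap outside stack, ...)."""


class OverpackedGeometryError(GeometryError):
    """Sphere placement could not terminate within the attempt budget."""


class DegenerateHistogramError(MicrocapError):
    """Otsu thresholding on a constant (single-valued) input."""


class NoHydrogelError(MicrocapError):
    """The CW channel carries no usable hydrogel signal."""


class CouponNotFoundError(MicrocapError):
    """No column of the stack shows a detectable coupon edge."""


class DomainEmptyError(MicrocapError):
    """A domain required for quantification contains no voxels."""


class UndefinedPartitionError(MicrocapError):
    """Partition coefficient undefined (zero or absent water signal)."""


class InsufficientTraceError(MicrocapError):
    """Too few time-lapse samples in the tail window for a plateau check."""


class DegenerateSampleError(MicrocapError):
    """A statistical sample with zero variance where variance is required."""


class DegenerateTestError(MicrocapError):
    """A two-sample test whose statistic is undefined (both variances zero)."""


class MissingConditionError(MicrocapError):
    """A hypothesis references experimental conditions absent from the dataset."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"conditions absent from dataset: {self.missing}")
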