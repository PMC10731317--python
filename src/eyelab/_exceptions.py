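"""Exception hierarchy shared across the pipeline."""


class EyelabError(Exception):
    """Base class for all package errors."""


class FormatError(EyelabError):
    """Input raster or table does not match the expected format."""


class DegenerateRegionError(EyelabError):
    """A mask region is empty (or became empty after highlight exclusion)."""

    def __init__(self, region: str, message: str | None = None):
        self.region = region
        super().__init__(message or f"region '{region}' contains no usable pixels")


class GamutError(EyelabError):
    """A requested LAB colour falls outside the sRGB gamut."""


class DegenerateDataError(EyelabError):
    """Statistical input carries no usable variation."""


class SampleSizeError(EyelabError):
    """Too few observations for the requested statistic."""


class GroupingError(EyelabError):
    """A required group level is absent from the data."""


class PairingError(EyelabError):
    """Paired comparison input has incomplete pairs."""

    def __init__(self, missing_ids, message: str | None = None):
        self.missing_ids = list(missing_ids)
        super().__init__(
            message or f"incomplete pairs for image_ids: {self.missing_ids}"
        )


class DegenerateItemError(EyelabError):
    """An item (column) is constant and cannot enter a correlation analysis."""


class CrossLoadingError(EyelabError):
    """An item loads above threshold on more than one factor."""

    def __init__(self, items, message: str | None = None):
        self.items = list(items)
        super().__init__(message or f"items load on multiple factors: {self.items}")


class CoverageError(EyelabError):
    """A stimulus has no raters (or an item→scale mapping is incomplete)."""


class RankError(EyelabError):
    """Within-group covariance is singular."""


class UniquenessError(EyelabError):
    """Duplicate key where uniqueness is required."""


class ConfigError(EyelabError):
    """Run configuration failed validation."""


class HeywoodWarning(UserWarning):
    """A factor solution produced a communality at or above 1."""


class CalibrationWarning(UserWarning):
    """Simulated responses saturate the response scale excessively."""


class SingularFitWarning(UserWarning):
    """A mixed-model variance component was estimated at the boundary."""
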