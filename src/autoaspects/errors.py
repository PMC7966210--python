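"""Exception hierarchy for autoaspects."""


class AutoAspectsError(Exception):
    """Base class for all package errors."""


class SizingError(AutoAspectsError):
    """Grid too small to place the requested synthetic regions."""


class SpecificationError(AutoAspectsError):
    """Invalid phantom or lesion specification."""


class EmptyRegionError(AutoAspectsError):
    """All support voxels of a region were excluded by the HU window."""

    def __init__(self, region, hemisphere):
        self.region = region
        self.hemisphere = hemisphere
        super().__init__(
            f"region {region}/{hemisphere}: no voxel within the HU inclusion "
            "window; weighted mean undefined"
        )


class RegistrationError(AutoAspectsError):
    """Atlas fitting failed (e.g. empty brain-tissue mask)."""


class InfeasibleThresholdError(AutoAspectsError):
    """No candidate threshold reaches the required specificity floor."""

    def __init__(self, min_specificity, max_achievable):
        self.min_specificity = min_specificity
        self.max_achievable = max_achievable
        super().__init__(
            f"no threshold reaches specificity >= {min_specificity:.3f}; "
            f"maximum achievable is {max_achievable:.3f}"
        )


class AlignmentError(AutoAspectsError):
    """Rating tables or paired score vectors do not align."""


class FormatError(AutoAspectsError):
    """Unreadable or malformed input file."""
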