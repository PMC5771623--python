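"""Exception hierarchy shared across the package."""


class LeafspecError(Exception):
    """Base class for all package-specific errors."""


class SpectrumParseError(LeafspecError):
    """A spectrum file row could not be parsed."""


class SpectrumFormatError(LeafspecError):
    """A spectrum violates a structural invariant (e.g. duplicate wavelengths)."""


class AlignmentError(LeafspecError):
    """Two spectra expected on a shared wavelength grid are not."""


class CalibrationError(LeafspecError):
    """Radiance-to-reflectance calibration is ill-posed (non-positive reference)."""


class ManifestError(LeafspecError):
    """A sample manifest is malformed or references missing files."""


class OutOfRangeError(LeafspecError):
    """A requested wavelength lies outside the spectrum's coverage."""


class ConfigurationError(LeafspecError):
    """An invalid pipeline/model configuration value."""
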