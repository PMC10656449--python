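"""Exception hierarchy.

All package errors derive from :class:`CollagenFFTError` so callers can
catch analysis failures without swallowing programming errors.
"""


class CollagenFFTError(Exception):
    """Base class for all collagenfft errors."""


class FormatError(CollagenFFTError):
    """Input file could not be parsed in any supported raster format."""


class CalibrationError(CollagenFFTError):
    """Physical calibration is inconsistent with the pixel grid (non-square pixels)."""


class DataError(CollagenFFTError):
    """Input contains invalid values (NaN/Inf or malformed numeric text)."""


class ParameterError(CollagenFFTError):
    """A parameter is outside its documented range."""


class ResolutionError(CollagenFFTError):
    """The requested analysis lacks spatial/spectral resolution (e.g. tile < 128 px,
    or a period band covering fewer than 3 frequency bins)."""


class NoPeakError(CollagenFFTError):
    """No first-harmonic peak exists in the searched profile band."""


class NoBandingError(CollagenFFTError):
    """No rotation produced a significant first-harmonic peak; the image has no
    detectable D-banding (e.g. structureless or pure-noise input)."""


class SamplingError(CollagenFFTError):
    """Requested spatial period violates the sampling theorem (< 2 px per cycle)."""


class LayoutError(CollagenFFTError):
    """Phantom specification cannot be laid out in the requested field of view."""


class ApertureUndefinedError(CollagenFFTError):
    """Arc aperture is undefined for scatter/empty tiles."""


class NoOrientationError(CollagenFFTError):
    """No orientation vector can be drawn for scatter/empty tiles."""


class DegenerateKappaError(CollagenFFTError):
    """Chance agreement equals 1 (all ratings in one category); kappa undefined."""


class RatingValidationError(CollagenFFTError):
    """Rating table violates its invariants."""
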