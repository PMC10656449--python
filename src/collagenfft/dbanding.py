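"""D-banding periodicity estimation by rotation-optimized PSD peak search.

The D-banding of a fibril population appears as a first-harmonic peak in
the image's power spectrum at the spatial frequency of the ~64 nm repeat.
Because fibril orientation varies between scans, the image is rotated to
bring the banding wave vector onto the profile axis, maximizing the
first-harmonic amplitude; the winning peak's bin index k then converts to a
period of N·Δx/k nanometres (N: analyzed side length, Δx: pixel size).

Peak significance
-----------------
An in-band maximum only counts as a harmonic peak if it stands far above
the in-band background: amplitude > median + 4·MAD of the in-band profile
values *and* > 50× the in-band median.  The joint rule makes the
"no detectable banding" outcome reproducible: genuine D-band peaks exceed
the in-band median by three to four orders of magnitude (≳10³ even at weak
contrast under heavy noise), while the maxima of exponential-tailed noise
spectra stay below ~25× of it even after maximizing over all rotations
(the MAD criterion alone passes white noise about half the time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .afm_io import AFMImage
from .errors import NoBandingError, NoPeakError, ResolutionError
from .spectral_core import (
    AxialProfile,
    axial_profile,
    band_to_bins,
    fft2d,
    psd,
    rotate_image,
)

__all__ = [
    "DBandResult",
    "find_first_harmonic",
    "bin_to_period",
    "optimize_rotation",
    "estimate_dband",
    "DEFAULT_PERIOD_BAND_NM",
]

#: default physiological search band, bracketing the 64–67 nm literature range
DEFAULT_PERIOD_BAND_NM: tuple[float, float] = (40.0, 110.0)

_MIN_ANALYSIS_PX = 128
_SIG_MAD_FACTOR = 4.0
_SIG_MEDIAN_RATIO = 50.0
_REFINE_TOL_DEG = 0.25


@dataclass(frozen=True)
class DBandResult:
    """Outcome of the rotation-optimized D-banding estimate.

    ``period_nm = n_px · pixel_size_nm / peak_bin`` holds exactly, where
    ``n_px`` is the side length of the analyzed (cropped, rotated) square.
    """

    period_nm: float
    rotation_deg: float
    peak_bin: int
    peak_amplitude: float
    n_px: int
    pixel_size_nm: float
    crop: tuple[int, int, int, int] | None = None
    profile: AxialProfile | None = None


def _band_bins(profile: AxialProfile, period_band_nm: tuple[float, float]) -> np.ndarray:
    k_lo, k_hi = band_to_bins(profile.n_px, profile.pixel_size_nm, period_band_nm)
    k_lo = max(k_lo, 2)  # DC/fundamental region excluded
    k_hi = min(k_hi, len(profile.values) - 1)
    return np.arange(k_lo, k_hi + 1)


def find_first_harmonic(
    profile: AxialProfile, period_band_nm: tuple[float, float] = DEFAULT_PERIOD_BAND_NM
) -> tuple[int, float]:
    """Locate the first-harmonic peak bin within a period band.

    Returns ``(peak_bin, peak_amplitude)``.  Ties break toward the lower
    bin, i.e. the longer period, for determinism under symmetric noise.
    """
    bins = _band_bins(profile, period_band_nm)
    if len(bins) < 3:
        raise ResolutionError(
            f"period band {period_band_nm} nm maps to {len(bins)} bins; need >= 3"
        )
    vals = profile.values[bins]
    if np.all(vals == 0.0):
        raise NoPeakError("no spectral energy in the period band")
    i = int(np.argmax(vals))  # argmax takes the first (lowest-bin) maximum
    return int(bins[i]), float(vals[i])


def _peak_is_significant(
    profile: AxialProfile, period_band_nm: tuple[float, float], amplitude: float
) -> bool:
    vals = profile.values[_band_bins(profile, period_band_nm)]
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    return amplitude > med + _SIG_MAD_FACTOR * mad and amplitude > _SIG_MEDIAN_RATIO * med


def bin_to_period(peak_bin: int, n_px: int, pixel_size_nm: float) -> float:
    """Convert a frequency bin index to a spatial period in nm."""
    if peak_bin == 0:
        raise ZeroDivisionError("the DC bin has no spatial period")
    return n_px * pixel_size_nm / peak_bin


def _evaluate_rotation(
    image: AFMImage,
    angle_deg: float,
    period_band_nm: tuple[float, float],
    window: str,
) -> tuple[float, int, float, AxialProfile, int] | None:
    """Objective for the rotation search.

    Returns (normalized_amplitude, peak_bin, raw_amplitude, profile, n_px)
    or None when the rotation yields no in-band peak.  The PSD peak of a
    coherent modulation scales with (M·N)², and the inscribed-square crop
    size varies with angle, so amplitudes are normalized by (M·N)² to be
    comparable across rotations.
    """
    rotated = rotate_image(image, angle_deg)
    spec_psd = psd(fft2d(rotated, window=window))
    prof = axial_profile(spec_psd, 0.0)
    try:
        k, amp = find_first_harmonic(prof, period_band_nm)
    except (NoPeakError, ResolutionError):
        return None
    n_px = rotated.n_cols
    return amp / float(n_px * rotated.n_rows) ** 2, k, amp, prof, n_px


def optimize_rotation(
    image: AFMImage,
    coarse_step_deg: float = 2.0,
    period_band_nm: tuple[float, float] = DEFAULT_PERIOD_BAND_NM,
    window: str = "hann",
) -> DBandResult:
    """Grid-search rotations in [0°, 180°) and refine to find the rotation
    maximizing the first-harmonic amplitude; convert the winning bin to nm.

    Coarse grid at ``coarse_step_deg`` followed by golden-section refinement
    to 0.25° around the winner.  Raises :class:`NoBandingError` when no
    rotation yields a significant in-band peak (e.g. structureless input).
    """
    if min(image.n_rows, image.n_cols) < _MIN_ANALYSIS_PX:
        raise ResolutionError(
            f"image side {min(image.n_rows, image.n_cols)} px < {_MIN_ANALYSIS_PX} px minimum"
        )
    evals: dict[float, tuple] = {}

    def objective(angle: float) -> float:
        angle = float(angle)
        if angle not in evals:
            res = _evaluate_rotation(image, angle, period_band_nm, window)
            evals[angle] = res
        res = evals[angle]
        return -np.inf if res is None else res[0]

    angles = np.arange(0.0, 180.0, coarse_step_deg)
    scores = [objective(a) for a in angles]
    best_i = int(np.argmax(scores))
    if not np.isfinite(scores[best_i]):
        raise NoBandingError("no rotation produced an in-band first-harmonic peak")

    # golden-section refinement around the coarse winner
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    lo = float(angles[best_i]) - coarse_step_deg
    hi = float(angles[best_i]) + coarse_step_deg
    a, b = hi - phi * (hi - lo), lo + phi * (hi - lo)
    fa, fb = objective(a), objective(b)
    while hi - lo > _REFINE_TOL_DEG:
        if fa >= fb:
            hi, b, fb = b, a, fa
            a = hi - phi * (hi - lo)
            fa = objective(a)
        else:
            lo, a, fa = a, b, fb
            b = lo + phi * (hi - lo)
            fb = objective(b)

    best_angle = max((ang for ang, r in evals.items() if r is not None), key=objective)
    _, peak_bin, amplitude, prof, n_px = evals[best_angle]
    if not _peak_is_significant(prof, period_band_nm, amplitude):
        raise NoBandingError(
            "best first-harmonic candidate is not significant against the in-band background"
        )
    return DBandResult(
        period_nm=bin_to_period(peak_bin, n_px, image.pixel_size_nm),
        rotation_deg=best_angle % 180.0,
        peak_bin=peak_bin,
        peak_amplitude=amplitude,
        n_px=n_px,
        pixel_size_nm=image.pixel_size_nm,
        profile=prof,
    )


def estimate_dband(
    image: AFMImage,
    crop: tuple[int, int, int, int] | None = None,
    period_band_nm: tuple[float, float] = DEFAULT_PERIOD_BAND_NM,
    coarse_step_deg: float = 2.0,
    window: str = "hann",
) -> DBandResult:
    """Full D-banding pipeline: optional crop, then rotation-optimized PSD.

    ``crop`` is ``(row0, col0, rows, cols)``; its shorter side must be at
    least 128 px for the spectrum to resolve the first harmonic.
    """
    if crop is not None:
        r0, c0, rows, cols = crop
        if min(rows, cols) < _MIN_ANALYSIS_PX:
            raise ResolutionError(f"crop side {min(rows, cols)} px < {_MIN_ANALYSIS_PX} px")
        if r0 < 0 or c0 < 0 or r0 + rows > image.n_rows or c0 + cols > image.n_cols:
            raise ResolutionError("crop extends beyond the image")
        sub = image.pixels[r0 : r0 + rows, c0 : c0 + cols]
        image = AFMImage(
            pixels=sub,
            width_um=cols * image.pixel_size_nm / 1000.0,
            height_um=rows * image.pixel_size_nm / 1000.0,
        )
    result = optimize_rotation(
        image, coarse_step_deg=coarse_step_deg, period_band_nm=period_band_nm, window=window
    )
    if crop is not None:
        result = DBandResult(**{**result.__dict__, "crop": crop})
    return result
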