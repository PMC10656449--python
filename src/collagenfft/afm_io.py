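"""Reading calibrated AFM-style raster images and writing result tables.

AFM instruments export raster scans whose physical size (scan width in µm)
is not reliably carried by generic TIFF/PNG metadata, so the calibration is
always supplied by the caller.  Pixel values are kept in their native scale:
peak *locations* in the power spectrum are invariant to affine intensity
maps, and preserving raw values keeps energy (Parseval) checks meaningful.

Coordinate convention used throughout the package: row 0 is the top of the
image, x increases rightward along columns, y increases downward along rows;
angles are measured counterclockwise from the +x axis in the conventional
mathematical (y-up) frame and live on [0°, 180°).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Any, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import CalibrationError, DataError, FormatError

__all__ = ["AFMImage", "load_image", "save_text_image", "write_results", "export_spectrum_png"]

#: relative tolerance on pixel squareness: width_um/n_cols vs height_um/n_rows
_SQUARE_PIXEL_RTOL = 0.005


@dataclass(frozen=True)
class AFMImage:
    """A calibrated square-pixel AFM scan.

    Parameters
    ----------
    pixels
        2-D real-valued matrix in arbitrary deflection/height units.
    width_um, height_um
        Physical scan extent in micrometres.
    """

    pixels: np.ndarray
    width_um: float
    height_um: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise DataError(f"image must be 2-D with sides >= 2, got shape {px.shape}")
        if not (self.width_um > 0 and self.height_um > 0):
            raise CalibrationError("scan width/height must be positive")
        if not np.all(np.isfinite(px)):
            raise DataError("image contains non-finite values")
        sx = self.width_um / px.shape[1]
        sy = self.height_um / px.shape[0]
        if abs(sx - sy) > _SQUARE_PIXEL_RTOL * sx:
            raise CalibrationError(
                f"non-square pixels: {sx * 1000:.4f} nm (x) vs {sy * 1000:.4f} nm (y)"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def pixel_size_nm(self) -> float:
        """Physical pixel size in nm (identical along both axes)."""
        return self.width_um * 1000.0 / self.n_cols


def _load_raster(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        try:
            arr = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001 - wrap any reader failure
            raise FormatError(f"could not read TIFF {path}: {exc}") from exc
    elif suffix == ".png":
        try:
            with Image.open(path) as im:
                arr = np.asarray(im)
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"could not read PNG {path}: {exc}") from exc
    else:
        # whitespace- or comma-delimited numeric text, '#' comments
        try:
            text = path.read_text()
            delim = "," if "," in text.splitlines()[0].lstrip("# \t") or "," in text else None
            arr = np.loadtxt(path, delimiter=delim, comments="#")
        except OSError as exc:
            raise FormatError(f"could not read {path}: {exc}") from exc
        except ValueError as exc:
            raise DataError(f"malformed numeric text in {path}: {exc}") from exc
    if arr.ndim == 3:  # collapse RGB(A) to luminance-ish mean; AFM exports are grayscale
        arr = arr[..., :3].mean(axis=2)
    return np.asarray(arr, dtype=float)


def load_image(path: str | os.PathLike, width_um: float, height_um: float | None = None) -> AFMImage:
    """Load a TIFF/PNG/ASCII raster as a calibrated :class:`AFMImage`.

    Integer raster values are cast to float without rescaling.  If
    ``height_um`` is omitted the scan is assumed square.
    """
    p = Path(path)
    if not p.exists():
        raise FormatError(f"no such file: {p}")
    pixels = _load_raster(p)
    if not np.all(np.isfinite(pixels)):
        raise DataError(f"{p} contains NaN/Inf values")
    if height_um is None:
        height_um = width_um
    return AFMImage(pixels=pixels, width_um=width_um, height_um=height_um)


def save_text_image(image: AFMImage, path: str | os.PathLike) -> None:
    """Write the pixel matrix as whitespace-delimited text (lossless round-trip)."""
    np.savetxt(path, image.pixels, fmt="%.17g")


def _record_to_dict(rec: Any) -> dict[str, Any]:
    if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
        d = {}
        for f in dataclasses.fields(rec):
            v = getattr(rec, f.name)
            if isinstance(v, np.ndarray):
                v = v.tolist()
            elif isinstance(v, np.generic):
                v = v.item()
            elif dataclasses.is_dataclass(v) and not isinstance(v, type):
                continue  # nested heavy objects (profiles, spectra) are not tabulated
            d[f.name] = v
        return d
    if isinstance(rec, dict):
        return rec
    raise TypeError(f"cannot serialize record of type {type(rec)!r}")


def write_results(results: Sequence[Any] | Any, path: str | os.PathLike) -> None:
    """Write result records to CSV (tabular) or JSON (``.json`` path).

    ``results`` may be a single record or a sequence of dataclass records
    (``DBandResult``, ``TileClassification``, ``KappaResult``, ...).  Floats
    survive a CSV round trip to at least 6 significant digits (written with
    full repr precision).
    """
    if results is None:
        raise ValueError("results must be non-empty")
    if isinstance(results, dict) or (
        dataclasses.is_dataclass(results) and not isinstance(results, type)
    ):
        records: list[Any] = [results]
    else:
        records = list(results)  # type: ignore[arg-type]
    if not records:
        raise ValueError("results must be non-empty")
    dicts = [_record_to_dict(r) for r in records]
    p = Path(path)
    try:
        if p.suffix.lower() == ".json":
            payload = dicts[0] if len(dicts) == 1 else dicts
            p.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")
        else:
            pd.DataFrame(dicts).to_csv(p, index=False)
    except OSError as exc:
        raise IOError(f"cannot write results to {p}: {exc}") from exc


def _json_default(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _record_to_dict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def export_spectrum_png(psd: "PowerSpectrum2D", path: str | os.PathLike, log_scale: bool = True) -> None:
    """Render a DC-centered power spectrum as an 8-bit grayscale PNG.

    With ``log_scale`` the intensity is ``log(1+P)`` linearly rescaled to
    [0, 255]; this is how 2D-FFT images are conventionally displayed, since
    the DC/fundamental region dwarfs the harmonics on a linear scale.
    """
    power = np.asarray(psd.power, dtype=float)
    img = np.log1p(power) if log_scale else power
    lo, hi = float(img.min()), float(img.max())
    scaled = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    Image.fromarray((scaled * 255.0).round().astype(np.uint8)).save(Path(path))


if TYPE_CHECKING:  # pragma: no cover - avoids an import cycle at runtime
    from .spectral_core import PowerSpectrum2D  # noqa: F401
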