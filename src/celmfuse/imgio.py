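"""Image reading/writing and intensity normalization.

Internally every image is a float64 array in [0, 1]: grayscale rasters
are 2-D ``(rows, cols)``, color rasters 3-D ``(rows, cols, 3)`` RGB.
Files are read with imageio (PNG/TIFF, 8- or 16-bit) and written as
8-bit PNG with round-to-nearest quantization, so a read/write round
trip perturbs each pixel by at most 1/255.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

log = logging.getLogger(__name__)


class ImageFormatError(ValueError):
    """Raised when a file cannot be read as a supported image."""


def _bit_depth_max(arr: np.ndarray, path: Path) -> float:
    if arr.dtype == np.uint8:
        return 255.0
    if arr.dtype == np.uint16:
        return 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        # float TIFFs are assumed to already be normalized
        return 1.0
    raise ImageFormatError(f"{path}: unsupported sample type {arr.dtype}")


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF file into a float array scaled to [0, 1].

    Grayscale files yield a 2-D array, color files an ``(H, W, 3)`` RGB
    array.  An alpha channel, if present, is dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"no such image file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises various concrete types
        raise ImageFormatError(f"cannot read image {path}: {exc}") from exc
    scale = _bit_depth_max(arr, path)
    img = np.asarray(arr, dtype=np.float64) / scale
    if img.ndim == 3:
        if img.shape[2] in (2, 4):  # gray+alpha or RGBA
            log.warning("%s: dropping alpha channel", path)
            img = img[:, :, :-1]
        if img.shape[2] == 1:
            img = img[:, :, 0]
        elif img.shape[2] != 3:
            raise ImageFormatError(
                f"{path}: unsupported channel count {img.shape[2]}"
            )
    elif img.ndim != 2:
        raise ImageFormatError(f"{path}: unsupported dimensionality {img.ndim}")
    if not np.all(np.isfinite(img)):
        raise ImageFormatError(f"{path}: non-finite pixel values")
    return img


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] float image as 8-bit PNG (``round(v * 255)``).

    Values outside [0, 1] are clipped with a warning; they are legal only
    in intermediate difference images, which are never written.
    """
    path = Path(path)
    img = np.asarray(img, dtype=np.float64)
    if img.min() < 0.0 or img.max() > 1.0:
        log.warning(
            "%s: clipping values outside [0,1] (min=%g, max=%g)",
            path, img.min(), img.max(),
        )
        img = np.clip(img, 0.0, 1.0)
    data = np.rint(img * 255.0).astype(np.uint8)
    try:
        iio.imwrite(path, data, extension=path.suffix or ".png")
    except OSError as exc:
        raise OSError(f"cannot write image {path}: {exc}") from exc


def as_gray(img: np.ndarray) -> np.ndarray:
    """Return the luma plane of an image (identity for 2-D input)."""
    if img.ndim == 2:
        return img
    from .color import rgb_to_yuv

    return rgb_to_yuv(img)[0]
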