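"""YUV-space fusion path for color (SPECT-like) sources.

Pseudo-colored functional images carry their diagnostic information in
the color; fusing in RGB would mix channels and distort it.  Instead the
color image is split into luminance and chrominance (BT.601 full-range
YUV with the analog scale factors), the Y plane is fused with the
standard two-stage pipeline, and the U/V planes pass through — from the
single color source when only one input is colored, or selected
per-pixel by the final decision map when both are.
"""

from __future__ import annotations

import logging

import numpy as np

from .fusion import FusionResult, fuse_pipeline
from .train import FusionModel

log = logging.getLogger(__name__)

# BT.601 luma weights and the analog U/V scale factors, pinned so that
# the transform pair is bit-exactly invertible in float
WR, WG, WB = 0.299, 0.587, 0.114
U_SCALE = 0.492
V_SCALE = 0.877

__all__ = ["rgb_to_yuv", "yuv_to_rgb", "fuse_color"]


def rgb_to_yuv(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split an ``(H, W, 3)`` RGB image into (Y, U, V) planes.

    Y = 0.299 R + 0.587 G + 0.114 B; U = 0.492 (B - Y); V = 0.877 (R - Y).
    Y lies in [0, 1] for valid RGB; U and V are signed offsets.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB, got shape {img.shape}")
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    y = WR * r + WG * g + WB * b
    u = U_SCALE * (b - y)
    v = V_SCALE * (r - y)
    return y, u, v


def yuv_to_rgb(
    y: np.ndarray, u: np.ndarray, v: np.ndarray, clip: bool = True
) -> np.ndarray:
    """Exact float inverse of :func:`rgb_to_yuv`; optionally clip to [0, 1]."""
    y = np.asarray(y, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    r = y + v / V_SCALE
    b = y + u / U_SCALE
    g = (y - WR * r - WB * b) / WG
    rgb = np.stack([r, g, b], axis=-1)
    if clip:
        low, high = rgb.min(), rgb.max()
        if low < -1e-9 or high > 1 + 1e-9:
            log.info(
                "clipping RGB values outside [0,1] after fusion "
                "(min=%g, max=%g)", low, high,
            )
        rgb = np.clip(rgb, 0.0, 1.0)
    return rgb


def fuse_color(
    a: np.ndarray,
    b: np.ndarray,
    model: FusionModel,
    stride: int | None = None,
    exact: bool = False,
) -> tuple[np.ndarray, FusionResult]:
    """Fuse a pair where either input may be RGB.

    Returns the fused image (RGB if any input was RGB, else grayscale)
    together with the full luminance-pipeline audit record.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape[:2] != b.shape[:2]:
        raise ValueError(
            f"source images differ in size: {a.shape[:2]} vs {b.shape[:2]}"
        )
    a_color = a.ndim == 3
    b_color = b.ndim == 3
    if not (a_color or b_color):
        result = fuse_pipeline(a, b, model, stride=stride, exact=exact)
        return result.ff, result

    if a_color:
        ya, ua, va = rgb_to_yuv(a)
    else:
        ya, ua, va = a, np.zeros_like(a), np.zeros_like(a)
    if b_color:
        yb, ub, vb = rgb_to_yuv(b)
    else:
        yb, ub, vb = b, np.zeros_like(b), np.zeros_like(b)

    result = fuse_pipeline(ya, yb, model, stride=stride, exact=exact)

    if a_color and b_color:
        # both colored: chrominance follows the per-pixel provenance of Y
        u = np.where(result.provenance == 1, ua, ub)
        v = np.where(result.provenance == 1, va, vb)
    elif a_color:
        u, v = ua, va
    else:
        u, v = ub, vb
    return yuv_to_rgb(result.ff, u, v), result
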