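"""Stage 2 of the fusion: windowed-RMSE arbitration and morphology.

The initial fused image F is compared back against both sources through
the signed difference images F-A and F-B.  At each pixel the local
(5x5) RMSE between F-B and A is weighed against that between F-A and B:
if removing B's content from F still resembles A strongly, more of A's
information belongs at that pixel (binary map MF = 1).  MF is smoothed
by one binary opening followed by one closing with a flat 5x5 square
structuring element (MFF), and the final image FF re-selects a source
pixel only where the 3x3 neighbourhood of MFF is unanimous — a stricter
condition than stage 1's majority rule, because stage 2 only fine-tunes
an already plausible fusion.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi

from .stage1 import neighbor_sum

__all__ = ["windowed_rmse", "mf_map", "smooth_mm", "final_fuse"]


def windowed_rmse(x: np.ndarray, y: np.ndarray, win: int = 5) -> np.ndarray:
    """Local root-mean-square difference over a ``win x win`` window.

    ``out[i, j] = sqrt(mean((x - y)^2 over the neighbourhood))`` with
    replicate padding at the borders.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if win % 2 != 1 or win < 1:
        raise ValueError(f"window must be a positive odd integer, got {win}")
    sq = (x - y) ** 2
    # direct correlation (not a running-sum filter): windows of exact
    # zeros stay exactly zero, which the strict '>' in mf_map relies on
    kernel = np.full((win, win), 1.0 / (win * win))
    mean_sq = ndi.correlate(sq, kernel, mode="nearest")
    return np.sqrt(np.maximum(mean_sq, 0.0))


def mf_map(
    f: np.ndarray, a: np.ndarray, b: np.ndarray, win: int = 5
) -> np.ndarray:
    """Binary arbitration map: 1 where A deserves more weight than B.

    MF = 1 where the local RMSE between F and B strictly exceeds that
    between F and A — i.e. where F resembles A more than B, so A's
    information is what F carries there.  Ties give 0.

    Note: comparing RMS((F-B) - A) against RMS((F-A) - B) instead would
    be vacuous — the two arguments are the identical image F - A - B —
    which is why the arbitration is phrased as local similarity of F to
    each source.
    """
    f = np.asarray(f, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if not (f.shape == a.shape == b.shape):
        raise ValueError("shape mismatch between F and the sources")
    r_fb = windowed_rmse(f, b, win)
    r_fa = windowed_rmse(f, a, win)
    return (r_fb > r_fa).astype(np.int64)


_SE = np.ones((5, 5), dtype=bool)


def smooth_mm(mf: np.ndarray) -> np.ndarray:
    """Morphological smoothing: one opening then one closing, 5x5 square.

    Border convention: erosion pads with 1 and dilation with 0, so the
    padding never creates or destroys structure by itself.
    """
    m = np.asarray(mf).astype(bool)
    opened = ndi.binary_dilation(
        ndi.binary_erosion(m, structure=_SE, border_value=1),
        structure=_SE,
        border_value=0,
    )
    closed = ndi.binary_erosion(
        ndi.binary_dilation(opened, structure=_SE, border_value=0),
        structure=_SE,
        border_value=1,
    )
    return closed.astype(np.int64)


def final_fuse(
    f: np.ndarray, a: np.ndarray, b: np.ndarray, mff: np.ndarray
) -> np.ndarray:
    """Final selection: rewrite a pixel only on unanimous neighbourhoods.

    With s the 8-neighbour sum of MFF (replicate padded): FF = A where
    MFF = 1 and s = 8; FF = B where MFF = 0 and s = 0; otherwise FF
    keeps the stage-1 value F.
    """
    f = np.asarray(f, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    mff = np.asarray(mff)
    if not (f.shape == a.shape == b.shape == mff.shape):
        raise ValueError("shape mismatch in final fusion inputs")
    s = neighbor_sum(mff)
    take_a = (mff == 1) & (s == 8)
    take_b = (mff == 0) & (s == 0)
    return np.where(take_a, a, np.where(take_b, b, f))
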