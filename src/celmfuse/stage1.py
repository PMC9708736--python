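"""Stage 1 of the fusion: dense scoring, pixel selection, consistency.

The classifier is trained on 32x32 patches but applied densely: each
pixel's score comes from the patch centred on it (after reflect-padding
by half a patch).  Evaluating every patch independently would repeat
almost all convolution work, so scoring exploits that the network is
convolutional: the conv/pool stack is run ONCE over the whole padded
image and each patch's global-average-pooled feature is a 4x4 window
mean of the resulting feature maps.  With two stride-2 pooling layers
the pooling lattices of patch-wise and whole-image evaluation coincide
whenever the patch offset is a multiple of 4, so scores on the default
stride-4 grid (and, via the 16 sub-lattice shifts, at every pixel in
exact mode) are identical to patch-wise evaluation up to float
summation order.

Scores become a binary label map (1 = take the pixel from A), the label
map selects pixels, and a single-pass 3x3 consistency filter removes
isolated ownership decisions: if at least five of a pixel's eight
neighbours belong to A the pixel is taken from A, if at most three do
it is taken from B, and at exactly four it is left alone.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi

from .network import forward_conv_stack, patch_trace
from .train import FusionModel

__all__ = ["score_map", "label_map", "initial_fuse", "consistency_filter"]


def _gap_maps(image: np.ndarray, model: FusionModel) -> np.ndarray:
    """Sliding patch features of a padded image: ``(C, n_y, n_x)``.

    Entry ``[:, i, j]`` is the branch feature vector of the patch whose
    top-left corner sits at ``(4i, 4j)`` in ``image``.
    """
    config = model.config
    maps = forward_conv_stack(image, model.bank, config)  # (C, h, w)
    win = patch_trace(config)[-1]  # a patch's final conv-map side (4 for defaults)
    view = np.lib.stride_tricks.sliding_window_view(maps, (win, win), axis=(1, 2))
    return view.mean(axis=(-1, -2))


def score_map(
    a: np.ndarray,
    b: np.ndarray,
    model: FusionModel,
    stride: int | None = None,
    exact: bool = False,
) -> np.ndarray:
    """Per-pixel classifier scores in [0, 1]; 1 favours source A.

    Patches are evaluated on a grid of the given stride (default from
    the model config) and upsampled to full resolution by nearest
    neighbour; ``exact=True`` forces stride 1 (every pixel scored).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"source images differ in size: {a.shape} vs {b.shape}")
    config = model.config
    h, w = a.shape
    p = config.patch_size
    if h < p or w < p:
        raise ValueError(f"images must be at least {p}x{p}, got {h}x{w}")
    s = 1 if exact else (stride if stride is not None else config.score_stride)
    if s < 1:
        raise ValueError(f"stride must be positive, got {s}")

    pad = p // 2
    a_pad = np.pad(a, pad, mode="reflect")
    b_pad = np.pad(b, pad, mode="reflect")

    ys = np.arange(0, h, s)
    xs = np.arange(0, w, s)
    half = config.conv_channels[-1]
    beta_a = model.elm.beta[:half]
    beta_b = model.elm.beta[half:]
    lattice = config.pool_stride**2  # alignment period of the two pools
    grid = np.empty((len(ys), len(xs)))
    for ry in np.unique(ys % lattice):
        sel_y = ys % lattice == ry
        for rx in np.unique(xs % lattice):
            sel_x = xs % lattice == rx
            ga = _gap_maps(a_pad[ry:, rx:], model)
            gb = _gap_maps(b_pad[ry:, rx:], model)
            raw = np.tensordot(beta_a, ga, axes=(0, 0)) + np.tensordot(
                beta_b, gb, axes=(0, 0)
            )
            iy = (ys[sel_y] - ry) // lattice
            ix = (xs[sel_x] - rx) // lattice
            grid[np.ix_(sel_y, sel_x)] = raw[np.ix_(iy, ix)]
    grid = np.clip(grid, 0.0, 1.0)

    rows = np.clip(np.rint(np.arange(h) / s).astype(int), 0, len(ys) - 1)
    cols = np.clip(np.rint(np.arange(w) / s).astype(int), 0, len(xs) - 1)
    return grid[np.ix_(rows, cols)]


def label_map(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize scores: 1 where ``score >= threshold`` (ties go to A)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0,1), got {threshold}")
    return (np.asarray(scores) >= threshold).astype(np.int64)


def initial_fuse(
    a: np.ndarray, b: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel selection: F = A where label 1, else B.

    Returns the fused image and the consistency matrix C, which simply
    records the ownership (equal to the label map by construction).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    labels = np.asarray(labels)
    if not (a.shape == b.shape == labels.shape):
        raise ValueError("shape mismatch between sources and label map")
    f = np.where(labels == 1, a, b)
    return f, (labels == 1).astype(np.int64)


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def neighbor_sum(binary: np.ndarray) -> np.ndarray:
    """Sum of the eight neighbours of each pixel, replicate-padded."""
    return ndi.correlate(
        np.asarray(binary, dtype=np.int64), _NEIGHBOR_KERNEL, mode="nearest"
    )


def consistency_filter(
    c: np.ndarray, a: np.ndarray, b: np.ndarray, f: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Majority-style cleanup of the ownership map, single pass.

    All neighbour sums are computed from the ORIGINAL map, so updates
    never cascade and the result is independent of scan order.
    """
    c = np.asarray(c)
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    f = np.asarray(f, dtype=np.float64)
    if not (c.shape == a.shape == b.shape == f.shape):
        raise ValueError("shape mismatch in consistency filter inputs")
    s = neighbor_sum(c)
    take_a = s >= 5
    take_b = s <= 3
    f_out = np.where(take_a, a, np.where(take_b, b, f))
    c_out = np.where(take_a, 1, np.where(take_b, 0, c)).astype(np.int64)
    return f_out, c_out
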