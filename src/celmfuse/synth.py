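"""Synthetic training corpora and evaluation phantoms.

Real multimodal pairs (CT/MRI atlases) are not redistributable, so the
package trains and validates on stand-ins:

* **training pairs** — a sharp 1/f-texture patch versus a Gaussian-blurred
  copy of itself.  Exactly one member of each pair is information-rich by
  construction, giving unambiguous 0/1 labels for the patch classifier.
* **phantom pairs** — two co-registered synthetic "modalities" with
  spatially complementary content: image A carries a bright skeletal
  ring plus sharp line structures (CT-like), image B smooth textured
  soft-tissue blobs (MRI-like), together with ground-truth masks of
  where each modality is the informative one.

Everything is a pure function of its seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.ndimage as ndi

from .config import RunConfig

__all__ = [
    "TrainingSet",
    "PhantomPair",
    "make_texture",
    "make_training_set",
    "make_phantom_pair",
]


@dataclasses.dataclass(frozen=True)
class TrainingSet:
    """Labelled siamese patch pairs.

    ``labels[i] == 1`` iff ``patches_a[i]`` is the sharp (information
    rich) member; classes are balanced to within one sample.
    """

    patches_a: np.ndarray  # (N, p, p)
    patches_b: np.ndarray  # (N, p, p)
    labels: np.ndarray  # (N,) in {0, 1}
    sigmas: np.ndarray  # (N,) blur widths actually applied
    seed: int

    def __len__(self) -> int:
        return self.labels.shape[0]


@dataclasses.dataclass(frozen=True)
class PhantomPair:
    """Complementary two-modality phantom with ground-truth masks.

    ``mask_a`` and ``mask_b`` are disjoint and jointly cover every pixel
    where the two images differ materially.
    """

    image_a: np.ndarray
    image_b: np.ndarray
    mask_a: np.ndarray  # bool, where A is the informative source
    mask_b: np.ndarray  # bool, where B is the informative source
    seed: int


def make_texture(size: int, seed: int, spectral_exponent: float = 1.5) -> np.ndarray:
    """Spectral-synthesis noise with power spectrum ~ 1/f^gamma.

    gamma = 0 gives white noise; gamma around 1.5 gives the spatially
    correlated, natural-image-like texture used for training patches.
    Rescaled so min = 0 and max = 1 exactly.
    """
    if size < 2:
        raise ValueError("texture size must be at least 2")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((size, size))
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    radius = np.hypot(fy, fx)
    radius[0, 0] = 1.0  # DC passes unscaled; its value is irrelevant after rescale
    amplitude = radius ** (-spectral_exponent / 2.0)
    amplitude[0, 0] = 0.0
    tex = np.fft.ifft2(np.fft.fft2(white) * amplitude).real
    tex -= tex.min()
    peak = tex.max()
    if peak > 0:
        tex /= peak
    return tex


def make_training_set(
    n_pairs: int,
    config: RunConfig | None = None,
    seed: int = 0,
    blur_sigma_range: tuple[float, float] = (2.0, 4.0),
) -> TrainingSet:
    """Sharp-vs-blurred patch pairs with balanced labels.

    For each pair a fresh 1/f texture is synthesized, a ``patch_size``
    patch cut from it, and a copy blurred with a Gaussian of width
    sigma ~ Uniform(blur_sigma_range).  The sharp patch occupies slot A
    for exactly half the pairs (label 1), slot B otherwise (label 0).
    """
    if n_pairs < 2:
        raise ValueError("need at least two pairs")
    if config is None:
        config = RunConfig()
    p = config.patch_size
    rng = np.random.default_rng(seed)
    canvas = 2 * p  # cut patches from a larger texture for variety
    lo, hi = blur_sigma_range

    labels = np.zeros(n_pairs, dtype=np.int64)
    labels[: n_pairs // 2 + n_pairs % 2] = 1
    rng.shuffle(labels)

    patches_a = np.empty((n_pairs, p, p))
    patches_b = np.empty((n_pairs, p, p))
    sigmas = rng.uniform(lo, hi, size=n_pairs)
    for i in range(n_pairs):
        tex = make_texture(canvas, seed=int(rng.integers(0, 2**31)))
        y = int(rng.integers(0, canvas - p + 1))
        x = int(rng.integers(0, canvas - p + 1))
        sharp = tex[y : y + p, x : x + p].copy()
        blurred = ndi.gaussian_filter(tex, sigmas[i], mode="reflect")[
            y : y + p, x : x + p
        ]
        if labels[i] == 1:
            patches_a[i], patches_b[i] = sharp, blurred
        else:
            patches_a[i], patches_b[i] = blurred, sharp
    return TrainingSet(
        patches_a=patches_a,
        patches_b=patches_b,
        labels=labels,
        sigmas=sigmas,
        seed=seed,
    )


def _disk(size: int, cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return np.hypot(yy - cy, xx - cx) <= radius


def make_phantom_pair(size: int = 256, seed: int = 0) -> PhantomPair:
    """Build one complementary phantom pair with ground-truth masks.

    Both images share a dim, smoothly varying background; they differ
    only inside the structure supports, so ``mask_a | mask_b`` covers
    every materially different pixel while ``mask_a & mask_b`` is empty.
    """
    if size < 64:
        raise ValueError("phantom size must be at least 64")
    rng = np.random.default_rng(seed)

    base = 0.12 + 0.06 * ndi.gaussian_filter(
        make_texture(size, seed=int(rng.integers(0, 2**31))), size / 16.0
    )

    # --- modality A: bright skeletal ring + sharp radial line structures
    cy, cx = size / 2.0, size / 2.0
    r_out = 0.42 * size
    r_in = 0.34 * size
    ring = _disk(size, cy, cx, r_out) & ~_disk(size, cy, cx, r_in)
    yy, xx = np.mgrid[0:size, 0:size]
    theta = np.arctan2(yy - cy, xx - cx)
    rad = np.hypot(yy - cy, xx - cx)
    spokes = np.zeros((size, size), dtype=bool)
    n_spokes = 6
    offset = rng.uniform(0, 2 * np.pi)
    for k in range(n_spokes):
        ang = offset + 2 * np.pi * k / n_spokes
        dtheta = np.angle(np.exp(1j * (theta - ang)))
        spokes |= (np.abs(dtheta) * rad < 2.5) & (rad > 0.10 * size) & (rad < r_in)
    struct_a = ring | spokes
    bone_tex = make_texture(size, seed=int(rng.integers(0, 2**31)), spectral_exponent=0.8)
    image_a = base.copy()
    image_a[struct_a] = 0.55 + 0.45 * bone_tex[struct_a]

    # --- modality B: smooth textured soft-tissue blobs inside the ring
    blob_support = np.zeros((size, size), dtype=bool)
    n_blobs = 5
    for _ in range(n_blobs):
        ang = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(0.05, 0.22) * size
        by, bx = cy + dist * np.sin(ang), cx + dist * np.cos(ang)
        blob_support |= _disk(size, by, bx, rng.uniform(0.08, 0.14) * size)
    blob_support &= _disk(size, cy, cx, r_in - 4)  # keep blobs off the ring
    # carve blobs away from A's structures (with margin) so the two
    # informative supports never overlap and ground truth is unambiguous
    blob_support &= ~ndi.binary_dilation(struct_a, iterations=4)
    soft_tex = make_texture(size, seed=int(rng.integers(0, 2**31)), spectral_exponent=1.2)
    # smooth ramp supported strictly inside the blobs, so B differs from
    # the shared background only within mask_b
    envelope = np.minimum(ndi.distance_transform_edt(blob_support) / 6.0, 1.0)
    image_b = base + envelope * (0.30 + 0.45 * soft_tex)
    image_b = np.clip(image_b, 0.0, 1.0)

    mask_a = struct_a
    mask_b = blob_support
    return PhantomPair(
        image_a=image_a,
        image_b=image_b,
        mask_a=mask_a,
        mask_b=mask_b,
        seed=seed,
    )
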