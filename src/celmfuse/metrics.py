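"""Objective fusion-quality metrics.

Four complementary views of how well a fused image F preserves the
content of its sources A and B:

* ``q_sf`` — spatial frequency of F alone (image-feature based): RMS of
  horizontal and vertical neighbour differences on the 0-255 scale;
  higher means more detail survived.
* ``q_piella`` — saliency-weighted universal quality index (structural
  similarity based): Wang-Bovik Q0 between each source and F over
  sliding 8x8 windows, weighted toward whichever source is locally more
  salient (higher variance).  1 is perfect.
* ``q_mi`` — entropy-normalized mutual information (information theory
  based): how much of each source's intensity distribution is
  predictable from F, bounded in [0, 2] with 2 at F == A == B.
* ``q_cv`` — Chen-Varshney perceptual distortion (human-vision based):
  regional mean squared source-minus-fusion error after filtering with
  the Mannos-Sakrison contrast sensitivity function, weighted by
  regional gradient saliency.  Lower is better, 0 at F == A == B.

All metrics operate on the luma plane for color images.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .imgio import as_gray

log = logging.getLogger(__name__)

__all__ = ["MetricReport", "MetricError", "q_sf", "q_piella", "q_mi", "q_cv", "evaluate"]


class MetricError(ValueError):
    """Raised when a metric is undefined for the given images."""


@dataclasses.dataclass(frozen=True)
class MetricReport:
    q_sf: float
    q_piella: float
    q_mi: float
    q_cv: float
    parameters: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def q_sf(f: np.ndarray) -> float:
    """Spatial frequency of the fused image on the 0-255 scale.

    RF/CF are the RMS horizontal/vertical first differences and
    ``Q_SF = sqrt(RF^2 + CF^2)``; a constant image scores 0.
    """
    f = as_gray(np.asarray(f, dtype=np.float64)) * 255.0
    if f.shape[0] < 2 and f.shape[1] < 2:
        raise MetricError("image must have at least one neighbouring pixel pair")
    rf2 = np.mean(np.diff(f, axis=1) ** 2) if f.shape[1] >= 2 else 0.0
    cf2 = np.mean(np.diff(f, axis=0) ** 2) if f.shape[0] >= 2 else 0.0
    return float(np.sqrt(rf2 + cf2))


def _window_stats(img: np.ndarray, win: int):
    """Sliding-window mean and population second moment, stride 1."""
    view = np.lib.stride_tricks.sliding_window_view(img, (win, win))
    mean = view.mean(axis=(-1, -2))
    sq = (view**2).mean(axis=(-1, -2))
    return view, mean, sq


def q_piella(a: np.ndarray, b: np.ndarray, f: np.ndarray, win: int = 8) -> float:
    """Piella-Heijmans weighted quality index Q_W over sliding windows.

    Per window: the universal quality index Q0 between each source and
    F, mixed by the saliency ratio lambda = var(A)/(var(A)+var(B)), and
    windows weighted by their total saliency.  Windows where Q0 is
    undefined count as perfect if the window pair is identical and are
    skipped otherwise.
    """
    a = as_gray(np.asarray(a, dtype=np.float64))
    b = as_gray(np.asarray(b, dtype=np.float64))
    f = as_gray(np.asarray(f, dtype=np.float64))
    if not (a.shape == b.shape == f.shape):
        raise MetricError("shape mismatch between sources and fused image")
    if min(a.shape) < win:
        raise MetricError(f"images must be at least {win}x{win}")

    n = win * win
    bessel = n / (n - 1)  # unbiased variance/covariance, per Wang-Bovik
    va_view, ma, sa = _window_stats(a, win)
    vb_view, mb, sb = _window_stats(b, win)
    vf_view, mf, sf = _window_stats(f, win)
    var_a = np.maximum(sa - ma**2, 0.0) * bessel
    var_b = np.maximum(sb - mb**2, 0.0) * bessel
    var_f = np.maximum(sf - mf**2, 0.0) * bessel
    cov_af = ((va_view * vf_view).mean(axis=(-1, -2)) - ma * mf) * bessel
    cov_bf = ((vb_view * vf_view).mean(axis=(-1, -2)) - mb * mf) * bessel

    def _q0(mx, my, vx, vy, cov, x_view, y_view):
        denom = (vx + vy) * (mx**2 + my**2)
        ok = denom > 0
        q0 = np.zeros_like(denom)
        q0[ok] = 4.0 * cov[ok] * mx[ok] * my[ok] / denom[ok]
        identical = np.zeros_like(ok)
        bad = ~ok
        if np.any(bad):
            identical[bad] = np.all(x_view[bad] == y_view[bad], axis=(-1, -2))
            q0[bad & identical] = 1.0
        usable = ok | identical
        return q0, usable

    q0_af, ok_af = _q0(ma, mf, var_a, var_f, cov_af, va_view, vf_view)
    q0_bf, ok_bf = _q0(mb, mf, var_b, var_f, cov_bf, vb_view, vf_view)
    usable = ok_af & ok_bf
    if not np.any(usable):
        raise MetricError("all windows degenerate; Piella metric undefined")
    n_skipped = usable.size - int(usable.sum())
    if n_skipped:
        log.info("q_piella: skipped %d degenerate windows", n_skipped)

    sal = var_a + var_b
    lam = np.full_like(sal, 0.5)
    pos = sal > 0
    lam[pos] = var_a[pos] / sal[pos]
    local_q = lam * q0_af + (1.0 - lam) * q0_bf
    weights = sal * usable
    total = weights.sum()
    if total == 0:
        # salient-free but consistent images: plain average over usable windows
        return float(local_q[usable].mean())
    return float((weights * local_q).sum() / total)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _quantize(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img * 255.0), 0, 255).astype(np.int64)


def q_mi(a: np.ndarray, b: np.ndarray, f: np.ndarray, bins: int = 256) -> float:
    """Entropy-normalized mutual information, bounded in [0, 2].

    ``2 * [I(A;F) / (H(A)+H(F)) + I(B;F) / (H(B)+H(F))]`` with 256-bin
    histograms on the 0-255 scale and entropies in bits.
    """
    a = as_gray(np.asarray(a, dtype=np.float64))
    b = as_gray(np.asarray(b, dtype=np.float64))
    f = as_gray(np.asarray(f, dtype=np.float64))
    if not (a.shape == b.shape == f.shape):
        raise MetricError("shape mismatch between sources and fused image")

    def _term(x: np.ndarray) -> float:
        joint, _, _ = np.histogram2d(
            _quantize(x).ravel(),
            _quantize(f).ravel(),
            bins=bins,
            range=[[-0.5, 255.5]] * 2,
        )
        joint /= joint.sum()
        hx = _entropy(joint.sum(axis=1))
        hf = _entropy(joint.sum(axis=0))
        hxf = _entropy(joint.ravel())
        if hx + hf == 0:  # both constant
            same = bool(np.array_equal(_quantize(x), _quantize(f)))
            log.info("q_mi: constant image pair, term defined as %d", int(same))
            return 1.0 if same else 0.0
        return (hx + hf - hxf) / (hx + hf)

    return float(2.0 * (_term(a) + _term(b)))


def _csf_filter(diff: np.ndarray, cpd_at_nyquist: float) -> np.ndarray:
    """Filter an image with the Mannos-Sakrison CSF in the frequency domain."""
    h, w = diff.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    rho = np.hypot(fy, fx) * (cpd_at_nyquist / 0.5)  # cycles/degree
    csf = 2.6 * (0.0192 + 0.114 * rho) * np.exp(-((0.114 * rho) ** 1.1))
    return np.fft.ifft2(np.fft.fft2(diff) * csf).real


def q_cv(
    a: np.ndarray,
    b: np.ndarray,
    f: np.ndarray,
    region: int = 16,
    cpd_at_nyquist: float = 30.0,
) -> float:
    """Chen-Varshney perceptual distortion (lower is better).

    The source-minus-fusion differences are CSF-filtered, their mean
    squared values taken over non-overlapping ``region x region``
    blocks, and averaged with weights given by each source's regional
    gradient-energy saliency.  Evaluated on the 0-255 scale.
    """
    a = as_gray(np.asarray(a, dtype=np.float64)) * 255.0
    b = as_gray(np.asarray(b, dtype=np.float64)) * 255.0
    f = as_gray(np.asarray(f, dtype=np.float64)) * 255.0
    if not (a.shape == b.shape == f.shape):
        raise MetricError("shape mismatch between sources and fused image")
    if min(a.shape) < region:
        raise MetricError(f"images must be at least {region}x{region}")

    def _blocks(img: np.ndarray) -> np.ndarray:
        h, w = img.shape
        hb, wb = h // region, w // region
        return (
            img[: hb * region, : wb * region]
            .reshape(hb, region, wb, region)
            .transpose(0, 2, 1, 3)
        )

    def _saliency(img: np.ndarray) -> np.ndarray:
        gy, gx = np.gradient(img)
        return _blocks(gy**2 + gx**2).sum(axis=(-1, -2))

    lam_a = _saliency(a)
    lam_b = _saliency(b)
    weight = lam_a + lam_b
    if weight.sum() == 0:
        raise MetricError("zero saliency everywhere; Chen-Varshney undefined")

    d_af = _blocks(_csf_filter(a - f, cpd_at_nyquist) ** 2).mean(axis=(-1, -2))
    d_bf = _blocks(_csf_filter(b - f, cpd_at_nyquist) ** 2).mean(axis=(-1, -2))
    return float((lam_a * d_af + lam_b * d_bf).sum() / weight.sum())


def evaluate(a: np.ndarray, b: np.ndarray, f: np.ndarray) -> MetricReport:
    """Compute all four metrics for a fused image against its sources."""
    params = {
        "piella_window": 8,
        "mi_bins": 256,
        "cv_region": 16,
        "cv_cpd_at_nyquist": 30.0,
    }
    return MetricReport(
        q_sf=q_sf(f),
        q_piella=q_piella(a, b, f),
        q_mi=q_mi(a, b, f),
        q_cv=q_cv(a, b, f),
        parameters=params,
    )
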