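"""The convolutional extreme learning machine (CELM).

A CELM is a CNN-shaped feature extractor whose convolution kernels are
*random* (drawn once from a zero-mean normal and never trained) and
whose only fitted parameters are the output weights ``beta`` of an
extreme-learning-machine head, solved in closed form by regularized
least squares::

    beta = (I / C + H^T H)^{-1} H^T T

where H stacks the random features of the training samples, T the
binary labels, and C the regularization coefficient.

Each siamese branch is conv(64) -> ReLU -> maxpool -> conv(128) -> ReLU
-> maxpool -> conv(256) -> ReLU -> global average pooling; the two
256-vectors are concatenated into the 512-dimensional feature the ELM
head scores.  On a 32x32 patch with 3x3 valid kernels and 2x2/2 pools
the spatial trace is 32 -> 30 -> 15 -> 13 -> 6 -> 4.

Convolution is plain cross-correlation (no kernel flip), "valid" (no
padding): a k x k input against an r x r kernel yields (k - r + 1) on
each axis.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg

from .config import RunConfig

__all__ = [
    "KernelBank",
    "ELMModel",
    "init_kernel_bank",
    "conv_relu",
    "max_pool",
    "global_avg_pool",
    "branch_features",
    "pair_features",
    "batch_pair_features",
    "forward_conv_stack",
    "elm_fit",
    "elm_predict",
]


@dataclasses.dataclass(frozen=True)
class ConvLayer:
    """One random convolution layer: kernels ``(out, in, r, r)`` + biases."""

    kernels: np.ndarray
    biases: np.ndarray

    @property
    def out_channels(self) -> int:
        return self.kernels.shape[0]

    @property
    def kernel_size(self) -> int:
        return self.kernels.shape[-1]


@dataclasses.dataclass(frozen=True)
class KernelBank:
    """The full stack of random convolution layers, reproducible from seed."""

    layers: tuple[ConvLayer, ...]
    seed: int

    def channel_counts(self) -> tuple[int, ...]:
        return tuple(layer.out_channels for layer in self.layers)


@dataclasses.dataclass(frozen=True)
class ELMModel:
    """Fitted ELM head: output weights and the regularization used."""

    beta: np.ndarray  # (feature_dim,)
    C: float
    feature_dim: int

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=np.float64).reshape(-1)
        if beta.shape[0] != self.feature_dim:
            raise ValueError(
                f"beta length {beta.shape[0]} != feature_dim {self.feature_dim}"
            )
        if not np.all(np.isfinite(beta)):
            raise ValueError("non-finite entries in beta")
        object.__setattr__(self, "beta", beta)


def init_kernel_bank(config: RunConfig, seed: int | None = None) -> KernelBank:
    """Draw the random kernel bank.

    Entries are i.i.d. Normal(0, sigma^2) with sigma = 1/sqrt(fan_in),
    fan_in = in_channels * r^2 — variance-preserving scaling so that
    post-ReLU activations neither vanish nor blow up across layers.
    Biases are zero.  Identical (config, seed) reproduce the bank
    bit-exactly.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    r = config.kernel_size
    layers = []
    in_c = 1
    for out_c in config.conv_channels:
        fan_in = in_c * r * r
        sigma = 1.0 / np.sqrt(fan_in)
        kernels = rng.normal(0.0, sigma, size=(out_c, in_c, r, r))
        biases = np.zeros(out_c)
        layers.append(ConvLayer(kernels=kernels, biases=biases))
        in_c = out_c
    return KernelBank(layers=tuple(layers), seed=seed)


def _conv_valid_batch(x: np.ndarray, layer: ConvLayer) -> np.ndarray:
    """Valid cross-correlation of ``x (B, Cin, H, W)`` -> ``(B, Cout, H', W')``.

    im2col + GEMM: fast enough on one CPU for both patch batches and
    whole images, and bit-for-bit the literal double-sum definition up
    to float addition order.
    """
    b, cin, h, w = x.shape
    r = layer.kernel_size
    if h < r or w < r:
        raise ValueError(f"input {h}x{w} smaller than kernel {r}x{r}")
    win = np.lib.stride_tricks.sliding_window_view(x, (r, r), axis=(2, 3))
    # win: (B, Cin, H', W', r, r) -> columns (B*H'*W', Cin*r*r)
    hp, wp = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * hp * wp, cin * r * r)
    kmat = layer.kernels.reshape(layer.out_channels, cin * r * r)
    out = cols @ kmat.T + layer.biases
    return out.reshape(b, hp, wp, layer.out_channels).transpose(0, 3, 1, 2)


def conv_relu(stack: np.ndarray, layer: ConvLayer) -> np.ndarray:
    """Valid convolution of a ``(C, H, W)`` feature stack plus ReLU.

    Summation runs over all input channels; each output map is offset by
    its bias and rectified with ``max(0, .)``.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim == 2:
        stack = stack[None]
    out = _conv_valid_batch(stack[None], layer)[0]
    return np.maximum(out, 0.0)


def max_pool(stack: np.ndarray, size: int = 2, stride: int = 2) -> np.ndarray:
    """Per-channel block maximum; trailing rows/cols of odd inputs drop."""
    stack = np.asarray(stack, dtype=np.float64)
    squeeze = stack.ndim == 3
    if squeeze:
        stack = stack[None]
    b, c, h, w = stack.shape
    if size != stride:
        # general (overlapping) pooling, used only off the default path
        win = np.lib.stride_tricks.sliding_window_view(
            stack, (size, size), axis=(2, 3)
        )[:, :, ::stride, ::stride]
        out = win.max(axis=(-1, -2))
    else:
        ho, wo = h // stride, w // stride
        out = (
            stack[:, :, : ho * stride, : wo * stride]
            .reshape(b, c, ho, stride, wo, stride)
            .max(axis=(3, 5))
        )
    return out[0] if squeeze else out


def global_avg_pool(stack: np.ndarray) -> np.ndarray:
    """Per-channel spatial mean: ``(C, H, W) -> (C,)``."""
    stack = np.asarray(stack, dtype=np.float64)
    return stack.mean(axis=(-1, -2))


def _forward_batch(x: np.ndarray, bank: KernelBank, config: RunConfig) -> np.ndarray:
    """Run the conv/pool stack on ``(B, H, W)`` images -> ``(B, C, h, w)`` maps.

    The last convolution's rectified maps are returned *before* global
    average pooling so that callers can pool over patch-sized windows.
    """
    x = np.asarray(x, dtype=np.float64)[:, None]  # (B, 1, H, W)
    n_layers = len(bank.layers)
    for i, layer in enumerate(bank.layers):
        x = np.maximum(_conv_valid_batch(x, layer), 0.0)
        if i < n_layers - 1:
            x = max_pool(x, config.pool_size, config.pool_stride)
    return x


def forward_conv_stack(image: np.ndarray, bank: KernelBank, config: RunConfig) -> np.ndarray:
    """Whole-image conv/pool stack: ``(H, W) -> (C, h, w)`` feature maps."""
    return _forward_batch(np.asarray(image)[None], bank, config)[0]


def branch_features(patch: np.ndarray, bank: KernelBank, config: RunConfig | None = None) -> np.ndarray:
    """Feature vector of one branch for a ``patch_size`` square patch."""
    if config is None:
        config = RunConfig()
    patch = np.asarray(patch, dtype=np.float64)
    if patch.shape != (config.patch_size, config.patch_size):
        raise ValueError(
            f"patch must be {config.patch_size}x{config.patch_size}, "
            f"got {patch.shape}"
        )
    return global_avg_pool(forward_conv_stack(patch, bank, config))


def pair_features(
    patch_a: np.ndarray,
    patch_b: np.ndarray,
    bank: KernelBank,
    config: RunConfig | None = None,
) -> np.ndarray:
    """Siamese features: both patches through the *same* bank, concatenated."""
    return np.concatenate(
        [branch_features(patch_a, bank, config), branch_features(patch_b, bank, config)]
    )


def batch_pair_features(
    patches_a: np.ndarray,
    patches_b: np.ndarray,
    bank: KernelBank,
    config: RunConfig,
    chunk: int = 128,
) -> np.ndarray:
    """Siamese features for ``(N, p, p)`` patch arrays -> ``(N, 2C)`` matrix.

    Processes in chunks to bound the im2col workspace.
    """
    patches_a = np.asarray(patches_a, dtype=np.float64)
    patches_b = np.asarray(patches_b, dtype=np.float64)
    if patches_a.shape != patches_b.shape:
        raise ValueError("patch arrays must have identical shapes")
    n = patches_a.shape[0]
    out = np.empty((n, config.feature_dim))
    half = config.conv_channels[-1]
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        fa = _forward_batch(patches_a[lo:hi], bank, config).mean(axis=(-1, -2))
        fb = _forward_batch(patches_b[lo:hi], bank, config).mean(axis=(-1, -2))
        out[lo:hi, :half] = fa
        out[lo:hi, half:] = fb
    return out


def patch_trace(config: RunConfig) -> tuple[int, ...]:
    """Spatial sizes through one branch, input included.

    Defaults give (32, 30, 15, 13, 6, 4): each valid convolution maps
    k -> k - r + 1, each pool maps k -> floor(k / stride).
    """
    sizes = [config.patch_size]
    k = config.patch_size
    for i in range(len(config.conv_channels)):
        k = k - config.kernel_size + 1
        sizes.append(k)
        if i < len(config.conv_channels) - 1:
            k = k // config.pool_stride
            sizes.append(k)
    return tuple(sizes)


def elm_fit(H: np.ndarray, T: np.ndarray, C: float) -> ELMModel:
    """Solve the regularized least-squares system for the output weights.

    ``(I/C + H^T H) beta = H^T T`` is symmetric positive definite for
    C > 0, so it is solved with a Cholesky factorization rather than an
    explicit inverse; the residual is checked to 1e-8 relative accuracy.
    """
    H = np.asarray(H, dtype=np.float64)
    T = np.asarray(T, dtype=np.float64).reshape(-1)
    if not (np.all(np.isfinite(H)) and np.all(np.isfinite(T))):
        raise ValueError("non-finite entries in the training data")
    if C <= 0:
        raise ValueError(f"regularization C must be positive, got {C}")
    if H.shape[0] != T.shape[0]:
        raise ValueError(f"H has {H.shape[0]} rows but T has {T.shape[0]}")
    d = H.shape[1]
    A = H.T @ H + np.eye(d) / C
    rhs = H.T @ T
    beta = scipy.linalg.solve(A, rhs, assume_a="pos")
    resid = np.max(np.abs(A @ beta - rhs))
    tol = 1e-8 * max(1.0, np.max(np.abs(rhs)))
    if resid > tol:
        raise np.linalg.LinAlgError(
            f"ridge system solved poorly: residual {resid:g} > {tol:g}"
        )
    return ELMModel(beta=beta, C=float(C), feature_dim=d)


def elm_predict(features: np.ndarray, model: ELMModel) -> float | np.ndarray:
    """Score features with the fitted head, clamped to [0, 1].

    Accepts a single ``(d,)`` vector (returns a float) or an ``(N, d)``
    matrix (returns an ``(N,)`` array).  The 0.5 decision threshold is
    applied downstream, in the label map.
    """
    features = np.asarray(features, dtype=np.float64)
    single = features.ndim == 1
    feats = features[None] if single else features
    if feats.shape[1] != model.feature_dim:
        raise ValueError(
            f"feature length {feats.shape[1]} != model dim {model.feature_dim}"
        )
    raw = feats @ model.beta
    clipped = np.clip(raw, 0.0, 1.0)
    return float(clipped[0]) if single else clipped
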