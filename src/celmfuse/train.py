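"""Training protocol and model persistence.

Training stacks the siamese features of every patch pair into the ELM
design matrix H, the 0/1 labels into T, and solves the ridge system in
one shot — there is no iterative optimization anywhere.  An 80/20
train/validation split (by pair, seeded) gives an honest accuracy
estimate which is logged, not asserted.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np

from .config import RunConfig
from .network import (
    ELMModel,
    ConvLayer,
    KernelBank,
    batch_pair_features,
    elm_fit,
    elm_predict,
    init_kernel_bank,
)
from .synth import TrainingSet

log = logging.getLogger(__name__)

_FORMAT_VERSION = "celmfuse-model-1"


@dataclasses.dataclass(frozen=True)
class FusionModel:
    """A trained fusion classifier: random kernel bank + fitted ELM head."""

    bank: KernelBank
    elm: ELMModel
    config: RunConfig
    training_fingerprint: str = ""

    def __post_init__(self) -> None:
        if self.elm.feature_dim != self.config.feature_dim:
            raise ValueError(
                f"ELM dimension {self.elm.feature_dim} inconsistent with "
                f"config feature_dim {self.config.feature_dim}"
            )
        if self.bank.channel_counts() != self.config.conv_channels:
            raise ValueError("kernel bank channels inconsistent with config")


def train_celm(
    train: TrainingSet,
    config: RunConfig | None = None,
    val_fraction: float = 0.2,
) -> FusionModel:
    """Fit a fusion model on a labelled patch-pair corpus.

    The kernel bank is drawn from ``config.seed``; only the ELM output
    weights are fitted.  Training and (if ``val_fraction > 0``)
    validation accuracy at threshold 0.5 are logged.
    """
    if config is None:
        config = RunConfig()
    labels = np.asarray(train.labels)
    if len(train) < 2 or len(np.unique(labels)) < 2:
        raise ValueError("training corpus must contain both classes")

    rng = np.random.default_rng(train.seed)
    order = rng.permutation(len(train))
    n_val = int(round(val_fraction * len(train)))
    val_idx, fit_idx = order[:n_val], order[n_val:]
    if len(np.unique(labels[fit_idx])) < 2:
        raise ValueError("train split lost a class; use a larger corpus")

    bank = init_kernel_bank(config)
    H = batch_pair_features(
        train.patches_a[fit_idx], train.patches_b[fit_idx], bank, config
    )
    model = elm_fit(H, labels[fit_idx].astype(float), config.elm_C)

    fit_acc = np.mean(
        (elm_predict(H, model) >= config.threshold) == (labels[fit_idx] == 1)
    )
    log.info("training accuracy %.3f on %d pairs", fit_acc, len(fit_idx))
    if n_val:
        Hv = batch_pair_features(
            train.patches_a[val_idx], train.patches_b[val_idx], bank, config
        )
        val_acc = np.mean(
            (elm_predict(Hv, model) >= config.threshold) == (labels[val_idx] == 1)
        )
        log.info("validation accuracy %.3f on %d pairs", val_acc, n_val)

    fingerprint = f"seed={train.seed};n={len(train)}"
    return FusionModel(
        bank=bank, elm=model, config=config, training_fingerprint=fingerprint
    )


def classify_pairs(
    model: FusionModel, patches_a: np.ndarray, patches_b: np.ndarray
) -> np.ndarray:
    """Predicted 0/1 labels for a batch of patch pairs."""
    H = batch_pair_features(patches_a, patches_b, model.bank, model.config)
    return (elm_predict(H, model.elm) >= model.config.threshold).astype(np.int64)


def save_model(model: FusionModel, path: str | Path) -> None:
    """Serialize a model to a single NumPy archive.

    Layout: a version string, the run configuration, the per-layer
    kernels/biases, and the ELM head (beta, C, feature_dim).
    """
    path = Path(path)
    arrays: dict[str, np.ndarray] = {
        "format": np.array(_FORMAT_VERSION),
        "n_layers": np.array(len(model.bank.layers)),
        "bank_seed": np.array(model.bank.seed),
        "beta": model.elm.beta,
        "elm_C": np.array(model.elm.C),
        "feature_dim": np.array(model.elm.feature_dim),
        "fingerprint": np.array(model.training_fingerprint),
        "config_patch_size": np.array(model.config.patch_size),
        "config_conv_channels": np.array(model.config.conv_channels),
        "config_kernel_size": np.array(model.config.kernel_size),
        "config_pool_size": np.array(model.config.pool_size),
        "config_pool_stride": np.array(model.config.pool_stride),
        "config_elm_C": np.array(model.config.elm_C),
        "config_seed": np.array(model.config.seed),
        "config_score_stride": np.array(model.config.score_stride),
        "config_threshold": np.array(model.config.threshold),
    }
    for i, layer in enumerate(model.bank.layers):
        arrays[f"layer{i}_kernels"] = layer.kernels
        arrays[f"layer{i}_biases"] = layer.biases
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path: str | Path) -> FusionModel:
    """Load a model saved by :func:`save_model`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such model file: {path}")
    with np.load(path, allow_pickle=False) as data:
        fmt = str(data["format"])
        if fmt != _FORMAT_VERSION:
            raise ValueError(f"{path}: unsupported model format {fmt!r}")
        config = RunConfig(
            patch_size=int(data["config_patch_size"]),
            conv_channels=tuple(int(c) for c in data["config_conv_channels"]),
            kernel_size=int(data["config_kernel_size"]),
            pool_size=int(data["config_pool_size"]),
            pool_stride=int(data["config_pool_stride"]),
            elm_C=float(data["config_elm_C"]),
            seed=int(data["config_seed"]),
            score_stride=int(data["config_score_stride"]),
            threshold=float(data["config_threshold"]),
        )
        layers = tuple(
            ConvLayer(
                kernels=data[f"layer{i}_kernels"], biases=data[f"layer{i}_biases"]
            )
            for i in range(int(data["n_layers"]))
        )
        bank = KernelBank(layers=layers, seed=int(data["bank_seed"]))
        elm = ELMModel(
            beta=data["beta"],
            C=float(data["elm_C"]),
            feature_dim=int(data["feature_dim"]),
        )
        fingerprint = str(data["fingerprint"])
    return FusionModel(
        bank=bank, elm=elm, config=config, training_fingerprint=fingerprint
    )
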