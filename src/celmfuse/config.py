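"""Run configuration for the fusion pipeline.

All tunables of the network and the decision pipeline live in one frozen
dataclass so that a run is a pure function of (inputs, config, seed).
Values can be loaded from a TOML file whose keys mirror the field names;
explicit keyword overrides (e.g. from CLI flags) win over file values.
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Hyper-parameters of the CELM network and the fusion pipeline.

    Parameters
    ----------
    patch_size
        Side of the square patches fed to the siamese network.  32 keeps
        the classifier context large enough while limiting blocky
        artifacts in the decision map.
    conv_channels
        Output channels of the three convolution layers.
    kernel_size
        Side of the (square, odd) convolution kernels.
    pool_size, pool_stride
        Max-pooling window and stride (2/2 halves the resolution twice).
    elm_C
        Ridge regularization coefficient of the ELM output layer; the
        penalty on the output weights is ``1/C``, so larger C means a
        weaker prior.
    seed
        Default seed for kernel-bank generation and data synthesis.
    score_stride
        Grid spacing (pixels) of the sliding-window classifier at
        inference; scores between grid points are filled in by nearest
        neighbour.  4 matches the alignment lattice of the two
        stride-2 pooling layers.
    threshold
        Classifier score above which a pixel is taken from source A.
    """

    patch_size: int = 32
    conv_channels: tuple[int, int, int] = (64, 128, 256)
    kernel_size: int = 3
    pool_size: int = 2
    pool_stride: int = 2
    elm_C: float = 1.0
    seed: int = 0
    score_stride: int = 4
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.patch_size % (self.pool_stride**2) != 0:
            raise ValueError(
                f"patch_size {self.patch_size} must be divisible by "
                f"pool_stride^2 = {self.pool_stride ** 2}"
            )
        if self.kernel_size % 2 != 1:
            raise ValueError(f"kernel_size must be odd, got {self.kernel_size}")
        if self.elm_C <= 0:
            raise ValueError(f"elm_C must be positive, got {self.elm_C}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must lie in (0,1), got {self.threshold}")
        if len(self.conv_channels) != 3:
            raise ValueError("conv_channels must have exactly three entries")
        object.__setattr__(self, "conv_channels", tuple(self.conv_channels))

    @property
    def feature_dim(self) -> int:
        """Length of the concatenated siamese feature vector (2 x GAP)."""
        return 2 * self.conv_channels[-1]

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conv_channels"] = list(d["conv_channels"])
        return d


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from an optional TOML file plus overrides."""
    values: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        values.update(data)
    values.update({k: v for k, v in overrides.items() if v is not None})
    if "conv_channels" in values:
        values["conv_channels"] = tuple(values["conv_channels"])
    return RunConfig(**values)
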