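"""End-to-end grayscale fusion pipeline with full audit trail."""

from __future__ import annotations

import dataclasses

import numpy as np

from .stage1 import consistency_filter, initial_fuse, label_map, score_map
from .stage2 import final_fuse, mf_map, neighbor_sum, smooth_mm
from .train import FusionModel


@dataclasses.dataclass(frozen=True)
class FusionResult:
    """Everything a run produced: images, decision maps, provenance.

    ``provenance`` records, for every pixel of the final image, which
    source supplied it (1 = A, 0 = B); since every selection step copies
    whole pixels, it is exact, not inferred.
    """

    scores: np.ndarray  # dense classifier scores in [0, 1]
    labels: np.ndarray  # stage-1 label map
    f_initial: np.ndarray  # F before consistency filtering
    f: np.ndarray  # F after consistency filtering
    consistency: np.ndarray  # filtered ownership map C'
    mf: np.ndarray  # stage-2 arbitration map
    mff: np.ndarray  # after morphological smoothing
    ff: np.ndarray  # final fused image
    provenance: np.ndarray  # 1 where FF(i,j) == A(i,j) by selection


def fuse_pipeline(
    a: np.ndarray,
    b: np.ndarray,
    model: FusionModel,
    stride: int | None = None,
    exact: bool = False,
) -> FusionResult:
    """Run both fusion stages on a grayscale pair.

    Every pixel of the result is a copied source pixel — the pipeline
    never blends intensities.
    """
    scores = score_map(a, b, model, stride=stride, exact=exact)
    labels = label_map(scores, model.config.threshold)
    f0, c = initial_fuse(a, b, labels)
    f1, c1 = consistency_filter(c, a, b, f0)
    mf = mf_map(f1, a, b)
    mff = smooth_mm(mf)
    ff = final_fuse(f1, a, b, mff)

    s = neighbor_sum(mff)
    take_a = (mff == 1) & (s == 8)
    take_b = (mff == 0) & (s == 0)
    provenance = np.where(take_a, 1, np.where(take_b, 0, c1)).astype(np.int64)

    return FusionResult(
        scores=scores,
        labels=labels,
        f_initial=f0,
        f=f1,
        consistency=c1,
        mf=mf,
        mff=mff,
        ff=ff,
        provenance=provenance,
    )
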