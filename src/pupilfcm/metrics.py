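"""Segmentation quality metrics: accuracy (AC), sensitivity (SE), specificity (SP).

With F_S the segmented pupil pixel set, F_T the ground-truth pupil set
and IE the image pixel count:

    AC = |F_T ∩ F_S| / |F_S|
    SE = |F_T ∩ F_S| / |F_T|
    SP = (IE - |F_T ∪ F_S|) / (IE - |F_T|)

Note that AC is *precision-like* — the fraction of segmented pixels that
are truly pupil — not the common pixelwise accuracy; SE is the recall of
true pupil pixels and SP the correct-rejection rate of non-pupil pixels.
An empty segmentation has an undefined AC (0/0) and is scored 0 by
convention: a detector that outputs nothing is maximally imprecise here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EvalMetrics", "evaluate"]


@dataclass(frozen=True)
class EvalMetrics:
    """AC/SE/SP plus the raw pixel counts they were computed from."""

    ac: float
    se: float
    sp: float
    n_image: int
    n_seg: int
    n_truth: int
    n_intersection: int
    n_union: int


def evaluate(seg: np.ndarray, truth: np.ndarray) -> EvalMetrics:
    """Compare a binary segmentation against a binary ground-truth mask.

    ``truth`` must be nonempty and not cover the full frame, otherwise the
    SE or SP denominator vanishes.
    """
    s = np.asarray(seg, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if s.shape != t.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {t.shape}")
    n_image = s.size
    n_truth = int(t.sum())
    if n_truth == 0 or n_truth == n_image:
        raise ValueError("ground truth must be nonempty and not full-frame")
    n_seg = int(s.sum())
    n_inter = int((s & t).sum())
    n_union = int((s | t).sum())
    ac = n_inter / n_seg if n_seg > 0 else 0.0
    se = n_inter / n_truth
    sp = (n_image - n_union) / (n_image - n_truth)
    return EvalMetrics(
        ac=ac,
        se=se,
        sp=sp,
        n_image=n_image,
        n_seg=n_seg,
        n_truth=n_truth,
        n_intersection=n_inter,
        n_union=n_union,
    )
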