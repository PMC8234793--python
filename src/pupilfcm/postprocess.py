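"""Turn a converged clustering into a pupil mask and pupil center.

The pupil is the darkest structure in the eye image, so the cluster with
the smallest center is the pupil class; its center value doubles as the
"pupil threshold" reported alongside the mask.  Binarization assigns each
gray level to the cluster in which it holds maximum membership — for a
cluster-independent prior this is simply the nearest center, so the mask
is a pure gray-level lookup table.  The pupil center is the centroid of
the largest connected mask component after a small morphological opening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .clustering import ClusterState

__all__ = ["PupilResult", "select_pupil_cluster", "binarize", "locate_pupil_center"]


@dataclass
class PupilResult:
    """Final segmentation output of the pipeline."""

    pupil_threshold: float  # the pupil cluster center
    mask: np.ndarray  # bool grid, True = pupil
    center: tuple[float, float] | None  # (row, col) or None if no component qualifies
    n_iter: int
    cluster_centers: np.ndarray


def select_pupil_cluster(centers: np.ndarray) -> int:
    """Index of the minimum cluster center (ties -> lowest index)."""
    c = np.asarray(centers)
    if c.size == 0:
        raise ValueError("empty center vector")
    return int(np.argmin(c))


def binarize(filtered: np.ndarray, state: ClusterState, pupil_idx: int) -> np.ndarray:
    """Binary pupil mask from the clustering of the filtered image.

    A pixel is pupil iff its gray level has maximum membership in the
    pupil cluster.  Membership decreases monotonically with the distance
    to a center, so maximum membership coincides with minimum |level - v|
    (lowest cluster index on ties), and the whole decision reduces to a
    256-entry lookup table — equal intensities always get equal labels.
    """
    img = np.asarray(filtered)
    levels = np.arange(256, dtype=float)
    dist = np.abs(levels[None, :] - np.asarray(state.centers, float)[:, None])
    lut = dist.argmin(axis=0)  # (256,) cluster label per gray level
    return lut[img.astype(np.int64)] == pupil_idx


def locate_pupil_center(
    mask: np.ndarray, min_area: int = 50
) -> tuple[float, float] | None:
    """Centroid of the largest connected pupil component.

    The mask is opened with a 3x3 structuring element to drop speckle,
    then 8-connected components are labeled and the largest one of area
    at least ``min_area`` yields the (row, col) centroid.  Returns
    ``None`` when no component qualifies.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return None
    eight = np.ones((3, 3), int)
    opened = ndimage.binary_opening(m, structure=np.ones((3, 3), bool))
    labels, n = ndimage.label(opened, structure=eight)
    if n == 0:
        return None
    sizes = ndimage.sum_labels(opened, labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes))
    if sizes[best] < min_area:
        return None
    r, c = ndimage.center_of_mass(labels == best + 1)
    return float(r), float(c)
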