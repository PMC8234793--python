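"""Gaussian global-distribution spatial prior.

The pupil is the darkest structure in an eye image, and pixels close to
its center of mass are more likely to be pupil than equally dark pixels
far away (eyelashes, shadows).  The prior encodes this as an isotropic
Gaussian weight field

    W(l) = (1 / sqrt(2*pi)) * exp(-||l - l_c||^2 / (2 sigma^2))

centered on a rough pupil-centroid estimate ``l_c``.  The weight peaks at
1/sqrt(2*pi) on the centroid and decays with Euclidean distance; ``sigma``
(default 3 px) controls how sharply.

The clustering stage works on the gray-level histogram rather than on
pixels, so the per-pixel field is reduced to a per-gray-level weight
vector: each occupied level receives the mean weight of its pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "PEAK_WEIGHT",
    "SpatialPrior",
    "estimate_pupil_centroid",
    "gaussian_weight",
    "build_prior",
    "reduce_to_gray_levels",
]

#: Peak value of the Gaussian weight, attained exactly at the centroid.
PEAK_WEIGHT = 1.0 / np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class SpatialPrior:
    """Per-pixel Gaussian weight field with its generating parameters."""

    weights: np.ndarray  # 2-D float array, one weight per pixel
    centroid: tuple[float, float]  # (row, col) of the estimated pupil centroid
    sigma: float


def estimate_pupil_centroid(
    image: np.ndarray,
    dark_fraction: float = 0.05,
    largest_component: bool = False,
) -> tuple[float, float]:
    """Estimate the pupil center of mass from the darkest pixels.

    The threshold is the largest gray level whose cumulative pixel
    fraction does not exceed ``dark_fraction`` (so at most that share of
    pixels is selected); when even the darkest occupied level is more
    populous than the fraction, that level is used, so the dark set is
    never empty.  The intensity-unweighted centroid of the selected
    pixels is returned.  With ``largest_component=True`` a second pass
    restricts the set to its largest 8-connected component, which guards
    against a dark distractor (e.g. a shadow) splitting the estimate.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if not 0.0 < dark_fraction < 1.0:
        raise ValueError("dark_fraction must lie in (0, 1)")
    counts = np.bincount(img.astype(np.int64).ravel(), minlength=256)
    cumfrac = counts.cumsum() / img.size
    qualifying = np.nonzero((cumfrac <= dark_fraction) & (counts.cumsum() > 0))[0]
    if qualifying.size:
        thr = int(qualifying[-1])
    else:
        thr = int(np.nonzero(counts)[0][0])  # darkest occupied level
    dark = img <= thr
    if largest_component:
        labels, n = ndimage.label(dark, structure=np.ones((3, 3), int))
        if n > 1:
            sizes = ndimage.sum_labels(dark, labels, index=np.arange(1, n + 1))
            dark = labels == (int(np.argmax(sizes)) + 1)
    rows, cols = np.nonzero(dark)
    return float(rows.mean()), float(cols.mean())


def gaussian_weight(
    pixel: tuple[float, float],
    centroid: tuple[float, float],
    sigma: float,
) -> float:
    """Gaussian membership-enhancement weight of a single pixel."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d2 = (pixel[0] - centroid[0]) ** 2 + (pixel[1] - centroid[1]) ** 2
    return float(PEAK_WEIGHT * np.exp(-d2 / (2.0 * sigma**2)))


def build_prior(
    image: np.ndarray,
    sigma: float = 3.0,
    dark_fraction: float = 0.05,
    centroid: tuple[float, float] | None = None,
    largest_component: bool = False,
) -> SpatialPrior:
    """Compute the full Gaussian weight field for an image.

    The centroid defaults to :func:`estimate_pupil_centroid` on the image
    itself; passing one explicitly skips the estimate.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if centroid is None:
        centroid = estimate_pupil_centroid(
            img, dark_fraction=dark_fraction, largest_component=largest_component
        )
    rows = np.arange(img.shape[0], dtype=float)[:, None]
    cols = np.arange(img.shape[1], dtype=float)[None, :]
    d2 = (rows - centroid[0]) ** 2 + (cols - centroid[1]) ** 2
    weights = PEAK_WEIGHT * np.exp(-d2 / (2.0 * sigma**2))
    return SpatialPrior(weights=weights, centroid=(float(centroid[0]), float(centroid[1])), sigma=float(sigma))


def reduce_to_gray_levels(
    prior: SpatialPrior,
    filtered: np.ndarray,
    floor_at_mean: bool = False,
) -> np.ndarray:
    """Reduce the per-pixel weight field to per-gray-level weights.

    For every gray level present in ``filtered`` the value is the
    arithmetic mean of the prior weights over pixels carrying that level;
    levels absent from the image receive the global mean weight.

    With ``floor_at_mean=True`` occupied levels are additionally floored
    at the global mean weight.  A sharply peaked prior (small ``sigma``)
    otherwise drives the weights of distant gray levels to the float64
    underflow regime, which makes every cluster-center update numerically
    degenerate; the floor extends the unoccupied-level fallback to those
    levels while preserving the near-centroid enhancement.

    Returns a length-256 float vector indexed by gray level.
    """
    flt = np.asarray(filtered)
    if flt.shape != prior.weights.shape:
        raise ValueError(
            f"shape mismatch: prior {prior.weights.shape} vs image {flt.shape}"
        )
    levels = flt.astype(np.int64).ravel()
    w = prior.weights.ravel()
    sums = np.bincount(levels, weights=w, minlength=256)
    counts = np.bincount(levels, minlength=256)
    mean_w = float(w.mean())
    values = np.full(256, mean_w)
    occ = counts > 0
    values[occ] = sums[occ] / counts[occ]
    if floor_at_mean:
        values = np.maximum(values, mean_w)
    return values
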