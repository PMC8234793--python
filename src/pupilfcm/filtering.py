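"""Adaptive local window filter with neighbor-reliability gating.

Every pixel is replaced by a weighted average over its 5x5 neighborhood,
where neighbors are first screened for reliability against a robust
reference value and then weighted by the product of a spatial and a
gray-level similarity coefficient.

For a window centered on pixel k with intensities x_r:

* reference  x_o = (x_c + mean) / 2, with x_c the window median — a
  reference robust to extreme values in the neighborhood;
* deviation  sigma_k = RMS of (x_r - x_o) over the 25 pixels;
* a neighbor is *reliable* iff |x_r - x_o| <= sigma_k;
* spatial coefficient  exp(-d) with d the Euclidean offset norm;
* gray coefficient     exp(-(x_o - x_r)^2 / (lambda_g * sigma_g^2)),
  where sigma_g^2 is the mean squared deviation of the *reliable*
  intensities from x_o and lambda_g (default 3) controls how strongly
  intensity differences suppress a neighbor;
* filtered value  xi_k = sum(C_kr * x_r) / sum(C_kr) over reliable r.

Unreliable neighbors carry zero weight, so impulse noise and pixels from
a different structure (e.g. a glint inside the pupil) do not leak into
the response, while genuine edges are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "WINDOW",
    "WindowStats",
    "FilterWeights",
    "IntensityHistogram",
    "window_stats",
    "spatial_coeff",
    "gray_coeff",
    "window_weights",
    "filter_pixel",
    "filter_image",
    "gray_histogram",
]

#: Side length of the (fixed) square filtering window.
WINDOW = 5
_PAD = WINDOW // 2
#: Guard below which the gray-level variance is treated as zero.
_EPS = 1e-6

# Spatial coefficients exp(-d) are constant over the window grid.
_DR = np.arange(WINDOW) - _PAD
_SPATIAL = np.exp(-np.hypot(_DR[:, None], _DR[None, :]))


@dataclass(frozen=True)
class WindowStats:
    """Reliability statistics of one 5x5 neighborhood."""

    values: np.ndarray  # (5, 5) float intensities
    reference: float  # x_o = (median + mean) / 2
    deviation: float  # sigma_k, RMS deviation from the reference
    reliable: np.ndarray  # (5, 5) bool, |x_r - x_o| <= sigma_k


@dataclass(frozen=True)
class FilterWeights:
    """Spatial, gray-level and combined window weights (zero where unreliable)."""

    spatial: np.ndarray
    gray: np.ndarray
    combined: np.ndarray


def window_stats(window: np.ndarray, center_mode: str = "median") -> WindowStats:
    """Reference value, deviation and reliability flags of a 5x5 window.

    ``center_mode`` selects the "middle value" entering the reference:
    ``"median"`` (the 13th order statistic, default) or ``"central"``
    (the geometric center pixel).
    """
    w = np.asarray(window, dtype=float)
    if w.shape != (WINDOW, WINDOW):
        raise ValueError(f"window must be {WINDOW}x{WINDOW}, got {w.shape}")
    if center_mode == "median":
        xc = float(np.median(w))
    elif center_mode == "central":
        xc = float(w[_PAD, _PAD])
    else:
        raise ValueError(f"unknown center_mode {center_mode!r}")
    xbar = float(w.mean())
    xo = (xc + xbar) / 2.0
    sigma = float(np.sqrt(((w - xo) ** 2).mean()))
    # Equality counts as reliable: only a deviation *greater* than sigma_k
    # disqualifies a neighbor (constant windows keep all 25 pixels).
    reliable = np.abs(w - xo) <= sigma
    return WindowStats(values=w, reference=xo, deviation=sigma, reliable=reliable)


def spatial_coeff(offset: tuple[int, int]) -> float:
    """Spatial weight exp(-d) for an in-window offset from the center."""
    dr, dc = offset
    if abs(dr) > _PAD or abs(dc) > _PAD:
        raise ValueError(f"offset {offset} outside the {WINDOW}x{WINDOW} window")
    return float(np.exp(-np.hypot(dr, dc)))


def gray_coeff(x_o: float, x_r: float, lambda_g: float, sigma_g: float) -> float:
    """Gray-level weight exp(-(x_o - x_r)^2 / (lambda_g sigma_g^2)).

    A vanishing gray-level deviation means the reliable neighborhood is
    flat; the coefficient is then 1 by convention.
    """
    if lambda_g <= 0:
        raise ValueError("lambda_g must be positive")
    s2 = float(sigma_g) ** 2
    if s2 <= _EPS:
        return 1.0
    return float(np.exp(-((x_o - x_r) ** 2) / (lambda_g * s2)))


def window_weights(stats: WindowStats, lambda_g: float = 3.0) -> FilterWeights:
    """Combined spatial x gray weights of one window; unreliable pixels get 0."""
    if lambda_g <= 0:
        raise ValueError("lambda_g must be positive")
    rel = stats.reliable
    diff2 = (stats.values - stats.reference) ** 2
    sg2 = float(diff2[rel].mean())  # at least one pixel is always reliable
    if sg2 <= _EPS:
        gray = np.ones_like(stats.values)
    else:
        gray = np.exp(-diff2 / (lambda_g * sg2))
    spatial = _SPATIAL * rel
    gray = gray * rel
    return FilterWeights(spatial=spatial, gray=gray, combined=spatial * gray)


def filter_pixel(stats: WindowStats, weights: FilterWeights) -> float:
    """Filter response xi_k of one window: the C_kr-weighted intensity mean.

    If every combined weight is zero (contractual fallback; unreachable
    with the variance guard) the original center intensity is returned.
    """
    total = float(weights.combined.sum())
    if total == 0.0:
        return float(stats.values[_PAD, _PAD])
    return float((weights.combined * stats.values).sum() / total)


def filter_image(
    image: np.ndarray,
    lambda_g: float = 3.0,
    center_mode: str = "median",
) -> np.ndarray:
    """Apply the adaptive local window filter to a whole image.

    Borders are handled by mirror (reflect) padding so every pixel owns a
    full 5x5 window.  Responses are rounded to integers in [0, 255], since
    the downstream clustering operates on integer gray levels.
    """
    if lambda_g <= 0:
        raise ValueError("lambda_g must be positive")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] < WINDOW or img.shape[1] < WINDOW:
        raise ValueError(f"image must be 2-D and at least {WINDOW}x{WINDOW}")
    padded = np.pad(img, _PAD, mode="reflect")
    win = sliding_window_view(padded, (WINDOW, WINDOW))  # (H, W, 5, 5)

    if center_mode == "median":
        xc = np.median(win, axis=(2, 3))
    elif center_mode == "central":
        xc = img
    else:
        raise ValueError(f"unknown center_mode {center_mode!r}")
    xbar = win.mean(axis=(2, 3))
    xo = ((xc + xbar) / 2.0)[:, :, None, None]

    diff2 = (win - xo) ** 2
    sigma_k = np.sqrt(diff2.mean(axis=(2, 3)))[:, :, None, None]
    rel = np.abs(win - xo) <= sigma_k

    nr = rel.sum(axis=(2, 3))
    sg2 = (diff2 * rel).sum(axis=(2, 3)) / nr
    safe = sg2 > _EPS
    denom = np.where(safe, lambda_g * sg2, 1.0)[:, :, None, None]
    gray = np.where(safe[:, :, None, None], np.exp(-diff2 / denom), 1.0)

    weights = _SPATIAL[None, None, :, :] * gray * rel
    total = weights.sum(axis=(2, 3))
    xi = np.where(total > 0, (weights * win).sum(axis=(2, 3)) / np.where(total > 0, total, 1.0), img)
    return np.clip(np.rint(xi), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class IntensityHistogram:
    """Gray-level histogram: pixel counts gamma_j over levels j = 0..255."""

    counts: np.ndarray  # length-256 int array

    @property
    def levels(self) -> np.ndarray:
        """Occupied gray levels (nonzero counts), ascending."""
        return np.nonzero(self.counts)[0]

    @property
    def n_levels(self) -> int:
        """Number of occupied gray levels."""
        return int((self.counts > 0).sum())

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())


def gray_histogram(image: np.ndarray) -> IntensityHistogram:
    """Histogram of an 8-bit image; counts sum to the pixel count."""
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    counts = np.bincount(img.astype(np.int64).ravel(), minlength=256)
    return IntensityHistogram(counts=counts)
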