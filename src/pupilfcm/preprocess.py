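"""Eye-image preprocessing: grayscale conversion, region-of-interest cropping
and contrast-limited adaptive histogram equalization (CLAHE).

The segmentation pipeline operates on 8-bit single-channel images.  Color
frames from an eye camera are reduced by the standard Rec. 601 luminance
weights, an optional rectangular crop narrows the frame to the eye region,
and CLAHE stretches the local contrast between the pupil and its
surroundings before clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure

__all__ = ["RectROI", "to_grayscale", "crop_roi", "apply_clahe"]

#: Rec. 601 luminance weights for R, G, B.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangular region of interest.

    Indices are 0-based; ``bottom`` and ``right`` are exclusive, so the
    cropped extent is ``(bottom - top) x (right - left)``.
    """

    top: int
    left: int
    bottom: int
    right: int

    def __post_init__(self) -> None:
        if not (0 <= self.top < self.bottom and 0 <= self.left < self.right):
            raise ValueError(f"degenerate ROI {self}")

    @property
    def height(self) -> int:
        return self.bottom - self.top

    @property
    def width(self) -> int:
        return self.right - self.left

    def validate(self, shape: tuple[int, int]) -> None:
        """Raise if the ROI is not fully inside an image of the given shape."""
        h, w = shape[:2]
        if self.bottom > h or self.right > w:
            raise ValueError(f"ROI {self} exceeds image bounds {h}x{w}")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert a raster image to 8-bit grayscale.

    Single-channel input is returned unchanged (as uint8).  Three-channel
    input is reduced by 0.299 R + 0.587 G + 0.114 B and rounded to the
    nearest integer.  Any other channel count is rejected.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        return arr.astype(np.uint8, copy=True)
    if arr.ndim == 3 and arr.shape[2] == 1:
        return arr[:, :, 0].astype(np.uint8, copy=True)
    if arr.ndim == 3 and arr.shape[2] == 3:
        gray = np.rint(arr.astype(float) @ _LUMA)
        return np.clip(gray, 0, 255).astype(np.uint8)
    raise ValueError(f"unsupported image shape {arr.shape}; expected 1 or 3 channels")


def crop_roi(image: np.ndarray, roi: RectROI) -> np.ndarray:
    """Extract a rectangular region; pixel values are copied unchanged."""
    img = np.asarray(image)
    roi.validate(img.shape)
    return img[roi.top : roi.bottom, roi.left : roi.right].copy()


def apply_clahe(
    image: np.ndarray,
    clip_limit: float = 0.01,
    tiles: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    Parameters
    ----------
    image:
        8-bit grayscale image.
    clip_limit:
        Normalized clipping limit in (0, 1] (scikit-image convention);
        higher values give more contrast.
    tiles:
        Number of contextual tiles along (rows, columns); the kernel size
        is the image extent divided by the tile count.

    The output is again an 8-bit image of identical shape, and the
    transform is deterministic for fixed parameters.  A constant image has
    no contrast to enhance and is returned unchanged.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if img.min() == img.max():
        return img.astype(np.uint8, copy=True)
    kernel = (max(1, img.shape[0] // tiles[0]), max(1, img.shape[1] // tiles[1]))
    out = exposure.equalize_adapthist(
        img.astype(np.uint8), kernel_size=kernel, clip_limit=clip_limit
    )
    return np.rint(out * 255).astype(np.uint8)
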