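"""Synthetic eye-image generator with exact ground truth.

Renders the structures that make pupil segmentation hard in practice:
a dark elliptical pupil, an iris annulus of intermediate intensity,
bright sclera, specular glints (possibly punching into the pupil),
dark eyelash strokes from the top edge, a horizontal illumination
gradient, and additive Gaussian noise.  Every image comes with its exact
pupil mask and true center, so each pipeline stage can be validated
without external data.

Glint disks overlapping the pupil are *excluded* from the truth mask:
a specular reflection occludes the pupil, it is not pupil tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

__all__ = ["EyeSpec", "SyntheticEye", "generate_eye", "generate_suite", "DIFFICULTIES"]

DIFFICULTIES = ("clean", "glint", "low_contrast", "lashes", "mixed")


@dataclass(frozen=True)
class EyeSpec:
    """Full parameterization of one synthetic eye image.

    Intensities are 8-bit gray levels and must satisfy
    pupil < iris < sclera; the pupil ellipse must lie inside the image.
    The seed fixes the rendered image bit-exactly.
    """

    shape: tuple[int, int] = (200, 200)
    pupil_center: tuple[float, float] | None = None  # None -> image center
    pupil_radii: tuple[float, float] = (26.0, 23.0)  # (row, col) semi-axes
    pupil_intensity: float = 15.0
    iris_radius: float = 70.0
    iris_intensity: float = 85.0
    sclera_intensity: float = 215.0
    glints: tuple[tuple[tuple[float, float], float, float], ...] = ()  # ((r,c), radius, intensity)
    n_lashes: int = 0
    lash_thickness: int = 2
    lash_intensity: float = 25.0
    gradient_amplitude: float = 15.0
    noise_sd: float = 4.0
    seed: int = 0

    def resolved_center(self) -> tuple[float, float]:
        if self.pupil_center is not None:
            return self.pupil_center
        return ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)

    def validate(self) -> None:
        if not self.pupil_intensity < self.iris_intensity < self.sclera_intensity:
            raise ValueError("intensities must satisfy pupil < iris < sclera")
        r0, c0 = self.resolved_center()
        ry, rx = self.pupil_radii
        h, w = self.shape
        if not (r0 - ry >= 0 and r0 + ry < h and c0 - rx >= 0 and c0 + rx < w):
            raise ValueError("pupil ellipse must lie inside the image")
        if ry <= 0 or rx <= 0:
            raise ValueError("pupil radii must be positive")


class SyntheticEye(NamedTuple):
    image: np.ndarray  # uint8 eye image
    mask: np.ndarray  # bool ground-truth pupil mask
    center: tuple[float, float]  # true pupil (ellipse) center
    spec: EyeSpec


def _draw_lashes(img: np.ndarray, spec: EyeSpec, rng: np.random.Generator) -> None:
    """Dark random-walk polylines growing down from the top edge, in place."""
    h, w = img.shape
    half = spec.lash_thickness // 2
    for _ in range(spec.n_lashes):
        col = float(rng.integers(0, w))
        length = int(rng.integers(h // 5, h // 2))
        for row in range(min(length, h)):
            col += float(rng.uniform(-1.2, 1.2))
            c = int(round(col))
            if not 0 <= c < w:
                break
            img[row, max(0, c - half) : min(w, c + half + 1)] = spec.lash_intensity


def generate_eye(spec: EyeSpec) -> SyntheticEye:
    """Render one eye image with its exact pupil mask and true center."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    rows = np.arange(h, dtype=float)[:, None]
    cols = np.arange(w, dtype=float)[None, :]
    r0, c0 = spec.resolved_center()
    ry, rx = spec.pupil_radii

    img = np.full((h, w), spec.sclera_intensity, dtype=float)
    iris = (rows - r0) ** 2 + (cols - c0) ** 2 <= spec.iris_radius**2
    img[iris] = spec.iris_intensity
    ellipse = ((rows - r0) / ry) ** 2 + ((cols - c0) / rx) ** 2 <= 1.0
    img[ellipse] = spec.pupil_intensity

    mask = ellipse.copy()
    for (gr, gc), grad, gint in spec.glints:
        disk = (rows - gr) ** 2 + (cols - gc) ** 2 <= grad**2
        img[disk] = gint
        mask &= ~disk

    if spec.n_lashes > 0:
        _draw_lashes(img, spec, rng)

    if spec.gradient_amplitude != 0:
        img += spec.gradient_amplitude * (cols / max(w - 1, 1) - 0.5)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=(h, w))

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SyntheticEye(image=image, mask=mask, center=(r0, c0), spec=spec)


def _random_spec(
    kind: str, rng: np.random.Generator, shape: tuple[int, int]
) -> EyeSpec:
    h, w = shape
    r0 = float(rng.uniform(0.42 * h, 0.58 * h))
    c0 = float(rng.uniform(0.42 * w, 0.58 * w))
    ry = float(rng.uniform(0.10, 0.15) * min(h, w))
    rx = float(ry * rng.uniform(0.85, 1.15))
    seed = int(rng.integers(2**31))

    if kind == "low_contrast":
        pupil = float(rng.uniform(10, 40))
        iris = float(rng.uniform(max(60.0, pupil + 15), 90))
        sclera = float(rng.uniform(160, 220))
        noise = 4.0
    else:
        pupil = float(rng.uniform(10, 25))
        iris = pupil + float(rng.uniform(60, 80))
        sclera = float(rng.uniform(200, 235))
        noise = float(rng.uniform(2, 4))

    spec = EyeSpec(
        shape=shape,
        pupil_center=(r0, c0),
        pupil_radii=(ry, rx),
        pupil_intensity=pupil,
        iris_radius=float(min(h, w) * rng.uniform(0.3, 0.38)),
        iris_intensity=iris,
        sclera_intensity=sclera,
        gradient_amplitude=float(rng.uniform(0, 15)),
        noise_sd=noise,
        seed=seed,
    )

    if kind == "glint":
        n_g = int(rng.integers(1, 4))
        glints = []
        for _ in range(n_g):
            # glint center inside the pupil so it actually occludes it
            gr = r0 + float(rng.uniform(-0.5, 0.5)) * ry
            gc = c0 + float(rng.uniform(-0.5, 0.5)) * rx
            glints.append(((gr, gc), float(rng.uniform(2.5, 5.5)), float(rng.uniform(245, 255))))
        spec = replace(spec, glints=tuple(glints))
    elif kind == "lashes":
        spec = replace(
            spec,
            n_lashes=int(rng.integers(3, 9)),
            lash_intensity=pupil + float(rng.uniform(0, 10)),
        )
    return spec


def generate_suite(
    n: int,
    difficulty: str = "mixed",
    seed: int = 0,
    shape: tuple[int, int] = (200, 200),
) -> list[SyntheticEye]:
    """Generate ``n`` reproducible eye images of a given difficulty preset.

    Presets: ``clean`` (pupil/iris contrast >= 60 gray levels, no
    distractors), ``glint`` (1-3 specular spots overlapping the pupil),
    ``low_contrast`` (pupil 10-40 vs iris 60-90), ``lashes`` (dark
    eyelash strokes at near-pupil intensity), ``mixed`` (cycles through
    the four).  The single seed fixes the entire suite.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if difficulty not in DIFFICULTIES:
        raise ValueError(f"difficulty must be one of {DIFFICULTIES}")
    rng = np.random.default_rng(seed)
    cycle = ("clean", "glint", "low_contrast", "lashes")
    out = []
    for i in range(n):
        kind = difficulty if difficulty != "mixed" else cycle[i % 4]
        out.append(generate_eye(_random_spec(kind, rng, shape)))
    return out
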