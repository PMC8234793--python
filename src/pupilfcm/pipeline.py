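"""End-to-end pupil segmentation pipeline and batch evaluation.

Stage order: grayscale -> (crop) -> CLAHE -> spatial prior -> adaptive
local filter -> gray histogram -> per-level prior reduction -> histogram
fuzzy c-means -> pupil cluster selection -> binarization -> center
localization.  Ablation modes drop the filter, the prior, or both (the
"classical" baseline, equivalent to plain FCM on the pixel list).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass

import imageio.v3 as iio
import numpy as np

from .clustering import FCMConfig, run_fcm
from .filtering import filter_image, gray_histogram
from .metrics import EvalMetrics, evaluate
from .postprocess import PupilResult, binarize, locate_pupil_center, select_pupil_cluster
from .preprocess import RectROI, apply_clahe, crop_roi, to_grayscale
from .prior import build_prior, reduce_to_gray_levels

__all__ = ["RunConfig", "METHODS", "segment_image", "segment", "evaluate_batch", "compare_methods"]

logger = logging.getLogger("pupilfcm")

#: Pipeline variants: the full method and its ablations.
METHODS = ("distribution", "no_filter", "no_prior", "classical")

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters in one validated bundle.

    Clustering defaults (5 clusters, fuzziness 2, 1000 iterations,
    tolerance 1e-4, 5x5 window, gray influence factor 3, prior width
    sigma = 3) are the method's standard experimental settings.
    """

    roi: RectROI | None = None
    use_clahe: bool = True
    clip_limit: float = 0.01
    tiles: tuple[int, int] = (8, 8)
    sigma: float = 3.0
    dark_fraction: float = 0.05
    lambda_g: float = 3.0
    center_mode: str = "median"
    window: int = 5
    n_clusters: int = 5
    fuzziness: float = 2.0
    max_iter: int = 1000
    tol: float = 1e-4
    seed: int = 0
    init: str = "spread"
    prior_floor: bool = True
    min_area: int = 50

    def __post_init__(self) -> None:
        if self.window != 5:
            raise ValueError("the local filter window is fixed at 5x5")
        if self.sigma <= 0 or self.lambda_g <= 0:
            raise ValueError("sigma and lambda_g must be positive")
        if not 0 < self.dark_fraction < 1:
            raise ValueError("dark_fraction must lie in (0, 1)")
        self.fcm_config()  # delegate clustering validation

    def fcm_config(self) -> FCMConfig:
        return FCMConfig(
            n_clusters=self.n_clusters,
            fuzziness=self.fuzziness,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.seed,
            init=self.init,
        )


def _preprocess(image: np.ndarray, config: RunConfig) -> np.ndarray:
    gray = to_grayscale(image)
    if config.roi is not None:
        gray = crop_roi(gray, config.roi)
    if config.use_clahe:
        gray = apply_clahe(gray, clip_limit=config.clip_limit, tiles=config.tiles)
    return gray


def segment_image(
    image: np.ndarray,
    config: RunConfig = RunConfig(),
    method: str = "distribution",
) -> tuple[PupilResult, dict]:
    """Segment the pupil in one image; returns the result and a JSON-able report.

    ``method`` selects the full pipeline (``"distribution"``) or an
    ablation: ``"no_filter"`` (prior only), ``"no_prior"`` (filter only,
    uniform prior), ``"classical"`` (plain histogram FCM, equivalent to
    classical per-pixel FCM).
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    use_filter = method in ("distribution", "no_prior")
    use_prior = method in ("distribution", "no_filter")

    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    gray = _preprocess(image, config)
    timings["preprocess"] = time.perf_counter() - t0
    logger.info("preprocess: %dx%d in %.3fs", *gray.shape, timings["preprocess"])

    t0 = time.perf_counter()
    prior_field = (
        build_prior(gray, sigma=config.sigma, dark_fraction=config.dark_fraction)
        if use_prior
        else None
    )
    timings["prior"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    filtered = (
        filter_image(gray, lambda_g=config.lambda_g, center_mode=config.center_mode)
        if use_filter
        else gray
    )
    timings["filter"] = time.perf_counter() - t0
    logger.info("filter (%s): %.3fs", "on" if use_filter else "off", timings["filter"])

    hist = gray_histogram(filtered)
    prior_levels = (
        reduce_to_gray_levels(prior_field, filtered, floor_at_mean=config.prior_floor)
        if prior_field is not None
        else None
    )

    t0 = time.perf_counter()
    state = run_fcm(hist, prior_levels, config.fcm_config())
    timings["clustering"] = time.perf_counter() - t0
    logger.info(
        "clustering: %d iterations, centers %s in %.3fs",
        state.n_iter,
        np.round(state.centers, 2),
        timings["clustering"],
    )

    idx = select_pupil_cluster(state.centers)
    mask = binarize(filtered, state, idx)
    center = locate_pupil_center(mask, min_area=config.min_area)
    if center is None:
        logger.warning("no pupil component of sufficient area found")

    result = PupilResult(
        pupil_threshold=float(state.centers[idx]),
        mask=mask,
        center=center,
        n_iter=state.n_iter,
        cluster_centers=np.asarray(state.centers),
    )
    converged = bool(
        state.objective_trace.size >= 2
        and abs(state.objective_trace[-1] - state.objective_trace[-2]) <= config.tol
    )
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "method": method,
        "pupil_threshold": result.pupil_threshold,
        "n_iterations": result.n_iter,
        "converged": converged,
        "pupil_center": list(center) if center is not None else None,
        "cluster_centers": [float(c) for c in np.sort(state.centers)],
        "mask_area": int(mask.sum()),
        "objective_trace": [float(j) for j in state.objective_trace],
        "config": _config_dict(config),
    }
    return result, report


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    if config.roi is not None:
        d["roi"] = [config.roi.top, config.roi.left, config.roi.bottom, config.roi.right]
    d["tiles"] = list(config.tiles)
    return d


def segment(
    image_path: str,
    config: RunConfig = RunConfig(),
    method: str = "distribution",
    mask_path: str | None = None,
    report_path: str | None = None,
) -> tuple[PupilResult, dict]:
    """File-based wrapper around :func:`segment_image` (PNG mask, JSON report)."""
    image = iio.imread(image_path)
    result, report = segment_image(image, config, method=method)
    if mask_path is not None:
        iio.imwrite(mask_path, (result.mask.astype(np.uint8)) * 255)
    if report_path is not None:
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2)
    return result, report


def evaluate_batch(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    pooled: bool = False,
) -> tuple[list[EvalMetrics], dict[str, float]]:
    """Evaluate (segmentation, truth) mask pairs; returns per-image metrics and means.

    By default the summary row is the arithmetic mean of per-image AC, SE
    and SP; with ``pooled=True`` the ratios are instead computed from the
    summed pixel counts across the batch.
    """
    if not pairs:
        raise ValueError("no mask pairs to evaluate")
    per_image = [evaluate(seg, truth) for seg, truth in pairs]
    if pooled:
        n_image = sum(m.n_image for m in per_image)
        n_seg = sum(m.n_seg for m in per_image)
        n_truth = sum(m.n_truth for m in per_image)
        n_inter = sum(m.n_intersection for m in per_image)
        n_union = sum(m.n_union for m in per_image)
        means = {
            "ac": n_inter / n_seg if n_seg else 0.0,
            "se": n_inter / n_truth,
            "sp": (n_image - n_union) / (n_image - n_truth),
        }
    else:
        means = {
            "ac": float(np.mean([m.ac for m in per_image])),
            "se": float(np.mean([m.se for m in per_image])),
            "sp": float(np.mean([m.sp for m in per_image])),
        }
    return per_image, means


def compare_methods(
    eyes: list,
    config: RunConfig = RunConfig(),
    methods: tuple[str, ...] = METHODS,
) -> dict[str, dict]:
    """Run several pipeline variants over (image, mask, center) triples.

    Returns, per method, the mean AC/SE/SP, the mean pupil-center error in
    pixels (over images where a center was found) and the mean iteration
    count — the shape of a method-comparison table.
    """
    out: dict[str, dict] = {}
    for method in methods:
        pairs = []
        errors = []
        iters = []
        for eye in eyes:
            image, truth, true_center = eye[0], eye[1], eye[2]
            result, _ = segment_image(image, config, method=method)
            pairs.append((result.mask, truth))
            iters.append(result.n_iter)
            if result.center is not None:
                err = float(np.hypot(result.center[0] - true_center[0],
                                     result.center[1] - true_center[1]))
                errors.append(err)
        _, means = evaluate_batch(pairs)
        out[method] = {
            **means,
            "center_error_px": float(np.mean(errors)) if errors else float("nan"),
            "n_localized": len(errors),
            "mean_iterations": float(np.mean(iters)),
        }
    return out
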