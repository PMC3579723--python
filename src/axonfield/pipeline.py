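"""End-to-end analysis: image -> vector table -> binned sample -> comparison.

The single-image stage chains the filter, ridge and field modules in the
canonical order: steerable filtering and closed-form orientation, saturation
detection, non-maximum suppression, the global two-times-median threshold,
orientation inpainting over saturated patches, direction disambiguation away
from the injected eye, 30 um normalized-convolution smoothing, curvature
from the curl, and a second suppression pass with the smoothed normals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import field as field_mod
from . import filters, ridge
from .config import PipelineConfig
from .image import RasterImage
from .registration import (
    BinnedSample,
    EmbryoLandmarks,
    bin_sample,
    mirror_if_needed,
    normalize_vectors,
)
from .stats import GroupComparison, compare_genotypes

log = logging.getLogger(__name__)

VECTOR_COLUMNS = [
    "x_px",
    "y_px",
    "x_um",
    "y_um",
    "orientation_rad",
    "direction_rad",
    "curv_direction_rad",
    "kappa_per_um",
    "response",
]


@dataclass
class AnalysisResult:
    """Everything the single-image stage produces."""

    vectors: pd.DataFrame
    orientation: filters.OrientationField
    direction: field_mod.DirectionField
    curvature: field_mod.CurvatureField
    final_mask: np.ndarray


def analyze_image(
    image: RasterImage,
    injection_point: tuple[float, float],
    config: PipelineConfig | None = None,
) -> AnalysisResult:
    """Run the full filter/ridge/field chain on one image."""
    config = config or PipelineConfig()
    px = image.pixel_size_um
    bank = filters.build_filter_bank(
        config.sigma_um, px, sigma_is_fwhm=config.sigma_is_fwhm
    )
    basis = filters.basis_responses(image, bank)
    orient = filters.dominant_orientation(basis)
    log.info("orientation field: %d candidate pixels", int(orient.mask.sum()))

    sat = ridge.detect_saturation(image) if image.saturation_level is not None else None
    orient = ridge.nonmax_suppress(orient, config.nms_flank_mode)
    log.info("after NMS: %d pixels", int(orient.mask.sum()))
    orient = ridge.median_threshold(image, orient, config.threshold_factor)
    log.info("after median threshold: %d pixels", int(orient.mask.sum()))
    if sat is not None and sat.any():
        orient = ridge.interpolate_saturated(orient, sat)
        log.info("after saturation inpainting: %d pixels", int(orient.mask.sum()))

    direction = field_mod.to_direction_field(orient, injection_point)
    smoothed = field_mod.smooth_direction_field(
        direction, config.smoothing_sigma_um, px
    )
    curvature = field_mod.curvature_from_curl(smoothed, px)

    if config.second_nms_target == "response":
        final_mask = field_mod.second_nonmax(
            smoothed, orient.response, config.nms_flank_mode
        )
    else:
        final_mask = field_mod.second_nonmax(
            smoothed, np.nan_to_num(curvature.magnitude), config.nms_flank_mode
        )
    final_mask &= curvature.mask
    log.info("final retained set: %d pixels", int(final_mask.sum()))

    ys, xs = np.nonzero(final_mask)
    vectors = pd.DataFrame(
        {
            "x_px": xs.astype(float),
            "y_px": ys.astype(float),
            "x_um": xs * px,
            "y_um": ys * px,
            "orientation_rad": orient.theta[ys, xs],
            "direction_rad": smoothed.direction[ys, xs],
            "curv_direction_rad": curvature.curvature_angle[ys, xs],
            "kappa_per_um": curvature.kappa[ys, xs],
            "response": orient.response[ys, xs],
        }
    )
    return AnalysisResult(vectors, orient, smoothed, curvature, final_mask)


def analyze_specimen(
    image: RasterImage,
    landmarks: EmbryoLandmarks,
    config: PipelineConfig | None = None,
    return_raw: bool = False,
):
    """Image -> vectors -> normalized frame -> binned summaries.

    Returns ``(normalized_vectors, binned_sample)``; with ``return_raw`` the
    image-frame per-pixel vector table is appended as a third element.
    """
    config = config or PipelineConfig()
    injection = (
        landmarks.left_eye if landmarks.injected_eye == "left" else landmarks.right_eye
    )
    result = analyze_image(image, injection, config)
    normalized = normalize_vectors(
        result.vectors, landmarks, image.pixel_size_um, config.chiasm_side
    )
    normalized = mirror_if_needed(normalized, landmarks)
    binned = bin_sample(
        normalized,
        config.grid(),
        specimen_id=landmarks.specimen_id,
        genotype=landmarks.genotype,
    )
    if return_raw:
        return normalized, binned, result.vectors
    return normalized, binned


def compare_cohorts(
    cohort_a: list[tuple[RasterImage, EmbryoLandmarks]],
    cohort_b: list[tuple[RasterImage, EmbryoLandmarks]],
    config: PipelineConfig | None = None,
    label_a: str = "A",
    label_b: str = "B",
) -> tuple[GroupComparison, list[BinnedSample], list[BinnedSample]]:
    """Full two-cohort comparison from raw images."""
    config = config or PipelineConfig()
    binned_a = [analyze_specimen(img, lm, config)[1] for img, lm in cohort_a]
    binned_b = [analyze_specimen(img, lm, config)[1] for img, lm in cohort_b]
    comparison = compare_genotypes(
        binned_a, binned_b, alpha=config.alpha, label_a=label_a, label_b=label_b
    )
    return comparison, binned_a, binned_b
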