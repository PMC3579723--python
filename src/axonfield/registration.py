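"""Landmark registration into the universal eye frame, and grid binning.

Every specimen is mapped by the unique rotation + uniform scale +
translation that sends the centre of the left eye to the origin and the
centre of the right eye to (1, 0) of a normalized coordinate system:

* ``m`` runs along the eye baseline (0 at the left eye, 1 at the right eye,
  so the head midline sits at m = 0.5);
* ``p`` is the perpendicular coordinate, positive on the side of the brain
  and chiasm (downward in a standard image with the eyes at the top).

Angles are changed by the rotation only; curvature magnitudes are rescaled
into rad per eye-distance unit so they are dimensionless in the common
frame.  Specimens injected in the right eye are mirrored (m -> 1 - m, with
the matching angle flips) so every specimen reads as left-eye-injected.

The statistical grid is 32 x 32 over m in [0.4, 0.6), p in [0.05, 0.25)
(half-open bins), the window that brackets the chiasm around the midline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import DegenerateLandmarksError, InvalidParameterError
from .stats import circular_mean

log = logging.getLogger(__name__)


@dataclass
class EmbryoLandmarks:
    """Operator-annotated eye centres for one specimen (pixel coordinates)."""

    left_eye: tuple[float, float]
    right_eye: tuple[float, float]
    injected_eye: str = "left"
    specimen_id: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        if tuple(self.left_eye) == tuple(self.right_eye):
            raise DegenerateLandmarksError(
                f"specimen {self.specimen_id!r}: eye landmarks coincide"
            )
        if self.injected_eye not in {"left", "right"}:
            raise InvalidParameterError(
                f"injected_eye must be 'left' or 'right', got {self.injected_eye!r}"
            )

    def eye_distance_px(self) -> float:
        (lx, ly), (rx, ry) = self.left_eye, self.right_eye
        return float(np.hypot(rx - lx, ry - ly))


@dataclass
class GridSpec:
    """The 32 x 32 analysis grid in normalized (m, p) coordinates.

    Rows index the posterior coordinate p, columns the mediolateral
    coordinate m; intervals are half-open on the high edge so the bins tile
    the region exactly.
    """

    n_rows: int = 32
    n_cols: int = 32
    m_range: tuple[float, float] = (0.4, 0.6)
    p_range: tuple[float, float] = (0.05, 0.25)

    @property
    def m_edges(self) -> np.ndarray:
        return np.linspace(*self.m_range, self.n_cols + 1)

    @property
    def p_edges(self) -> np.ndarray:
        return np.linspace(*self.p_range, self.n_rows + 1)

    @property
    def m_width(self) -> float:
        return (self.m_range[1] - self.m_range[0]) / self.n_cols

    @property
    def p_width(self) -> float:
        return (self.p_range[1] - self.p_range[0]) / self.n_rows

    def bin_indices(self, m: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(row, col, inside) for normalized positions; half-open bins."""
        col = np.floor((m - self.m_range[0]) / self.m_width).astype(int)
        row = np.floor((p - self.p_range[0]) / self.p_width).astype(int)
        inside = (
            (m >= self.m_range[0])
            & (m < self.m_range[1])
            & (p >= self.p_range[0])
            & (p < self.p_range[1])
        )
        return row, col, inside


@dataclass
class BinnedSample:
    """One specimen's per-bin summaries on the analysis grid.

    Angular means are NaN in empty bins (a circular mean of nothing is
    undefined); counts are 0 there.
    """

    count: np.ndarray
    mean_orientation: np.ndarray
    mean_curv_direction: np.ndarray
    mean_curv_magnitude: np.ndarray
    specimen_id: str = ""
    genotype: str = ""


@dataclass
class SimilarityTransform:
    """Left eye -> (0, 0), right eye -> (1, 0); angles rotate, scale is uniform.

    ``chiasm_side`` (+1 or -1) selects which side of the baseline carries
    positive p; +1 is the side of increasing image y (the brain, when eyes
    are at the top of the frame).
    """

    left_eye: tuple[float, float]
    right_eye: tuple[float, float]
    chiasm_side: int = 1

    def __post_init__(self) -> None:
        (lx, ly), (rx, ry) = self.left_eye, self.right_eye
        self._origin = complex(lx, ly)
        self._baseline = complex(rx, ry) - self._origin
        if self._baseline == 0:
            raise DegenerateLandmarksError("eye landmarks coincide")
        if self.chiasm_side not in (1, -1):
            raise InvalidParameterError("chiasm_side must be +1 or -1")

    @property
    def eye_distance_px(self) -> float:
        return abs(self._baseline)

    @property
    def rotation_rad(self) -> float:
        """Angle subtracted from every direction/orientation."""
        return float(np.angle(self._baseline))

    def apply_points(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        z = (np.asarray(x, dtype=float) + 1j * np.asarray(y, dtype=float) - self._origin) / self._baseline
        return z.real, self.chiasm_side * z.imag

    def apply_angle(self, angle: np.ndarray, period: float = 2.0 * np.pi) -> np.ndarray:
        a = np.asarray(angle, dtype=float) - self.rotation_rad
        if self.chiasm_side == -1:
            a = -a
        return np.mod(a, period)


def similarity_transform(
    landmarks: EmbryoLandmarks, chiasm_side: int = 1
) -> SimilarityTransform:
    """The eye-frame transform for one specimen."""
    return SimilarityTransform(landmarks.left_eye, landmarks.right_eye, chiasm_side)


#: canonical column names of a normalized vector table
NORMALIZED_COLUMNS = [
    "m",
    "p",
    "orientation_rad",
    "direction_rad",
    "curv_direction_rad",
    "curv_magnitude",
    "response",
]


def normalize_vectors(
    vectors: pd.DataFrame,
    landmarks: EmbryoLandmarks,
    pixel_size_um: float,
    chiasm_side: int = 1,
) -> pd.DataFrame:
    """Map a per-pixel vector table into the universal eye frame.

    Expects columns ``x_px, y_px, orientation_rad, direction_rad,
    curv_direction_rad, kappa_per_um, response``.  Curvature magnitude is
    rescaled to rad per eye-distance unit (multiplying by the physical eye
    distance), so it is invariant under magnification changes.
    """
    tr = similarity_transform(landmarks, chiasm_side)
    m, p = tr.apply_points(vectors["x_px"].to_numpy(), vectors["y_px"].to_numpy())
    eye_um = tr.eye_distance_px * pixel_size_um
    out = pd.DataFrame(
        {
            "m": m,
            "p": p,
            "orientation_rad": tr.apply_angle(
                vectors["orientation_rad"].to_numpy(), period=np.pi
            ),
            "direction_rad": tr.apply_angle(vectors["direction_rad"].to_numpy()),
            "curv_direction_rad": tr.apply_angle(
                vectors["curv_direction_rad"].to_numpy()
            ),
            "curv_magnitude": np.abs(vectors["kappa_per_um"].to_numpy()) * eye_um,
            "response": vectors["response"].to_numpy(),
        }
    )
    return out


def mirror_if_needed(vectors: pd.DataFrame, landmarks: EmbryoLandmarks) -> pd.DataFrame:
    """Reflect right-eye-injected specimens so all read as left-injected.

    The reflection is m -> 1 - m about the midline; directions and
    orientations flip their m-component (angle -> pi - angle in the matching
    period).  Applying it twice is the identity.
    """
    if landmarks.injected_eye == "left":
        return vectors
    out = vectors.copy()
    out["m"] = 1.0 - vectors["m"]
    out["orientation_rad"] = np.mod(np.pi - vectors["orientation_rad"], np.pi)
    out["direction_rad"] = np.mod(np.pi - vectors["direction_rad"], 2.0 * np.pi)
    out["curv_direction_rad"] = np.mod(
        np.pi - vectors["curv_direction_rad"], 2.0 * np.pi
    )
    return out


def bin_sample(
    vectors: pd.DataFrame,
    grid: GridSpec | None = None,
    specimen_id: str = "",
    genotype: str = "",
) -> BinnedSample:
    """Bin a normalized vector table into per-grid-square summaries.

    Vectors outside the region are discarded.  Orientations use the axial
    circular mean, curvature directions the ordinary circular mean, and
    curvature magnitudes the arithmetic mean.
    """
    grid = grid or GridSpec()
    row, col, inside = grid.bin_indices(
        vectors["m"].to_numpy(), vectors["p"].to_numpy()
    )
    shape = (grid.n_rows, grid.n_cols)
    count = np.zeros(shape, dtype=int)
    mean_ori = np.full(shape, np.nan)
    mean_cdir = np.full(shape, np.nan)
    mean_cmag = np.full(shape, np.nan)
    if inside.any():
        nbins = grid.n_rows * grid.n_cols
        flat = row[inside] * grid.n_cols + col[inside]
        count = np.bincount(flat, minlength=nbins).reshape(shape)

        def _circ(angles: np.ndarray, mult: float) -> np.ndarray:
            finite = np.isfinite(angles)
            cs = np.bincount(
                flat[finite], weights=np.cos(mult * angles[finite]), minlength=nbins
            )
            sn = np.bincount(
                flat[finite], weights=np.sin(mult * angles[finite]), minlength=nbins
            )
            n = np.bincount(flat[finite], minlength=nbins)
            with np.errstate(invalid="ignore", divide="ignore"):
                rbar = np.hypot(cs, sn) / n
                mean = np.mod(np.arctan2(sn, cs) / mult, 2.0 * np.pi / mult)
            mean[(n == 0) | (rbar < 1e-9)] = np.nan
            return mean.reshape(shape)

        ori = vectors["orientation_rad"].to_numpy()[inside]
        cdir = vectors["curv_direction_rad"].to_numpy()[inside]
        cmag = vectors["curv_magnitude"].to_numpy()[inside]
        mean_ori = _circ(ori, 2.0)
        mean_cdir = _circ(cdir, 1.0)
        finite = np.isfinite(cmag)
        sums = np.bincount(flat[finite], weights=cmag[finite], minlength=nbins)
        ns = np.bincount(flat[finite], minlength=nbins)
        with np.errstate(invalid="ignore"):
            mean_cmag = (sums / ns).reshape(shape)
    return BinnedSample(count, mean_ori, mean_cdir, mean_cmag, specimen_id, genotype)


def cohort_heatmap(samples: list[BinnedSample]) -> np.ndarray:
    """Element-wise mean vector count per bin across specimens."""
    if not samples:
        raise InvalidParameterError("cohort_heatmap needs at least one sample")
    return np.mean([s.count for s in samples], axis=0)


@dataclass
class EyeDistanceReport:
    """Inter-eye distance QC across cohorts."""

    cohort_means: dict
    max_relative_difference: float
    limit: float
    flagged: bool


def eye_distance_qc(
    cohorts: dict[str, list[EmbryoLandmarks]],
    pixel_size_um: float = 1.0,
    limit: float = 0.08,
) -> EyeDistanceReport:
    """Compare mean inter-eye distances between cohorts.

    The reported figure is the largest pairwise relative difference between
    cohort means (difference over the smaller mean); it is flagged when it
    exceeds ``limit`` (default 8%, the variation tolerated in practice for
    comparably-staged embryos).
    """
    if len(cohorts) < 2:
        raise InvalidParameterError("eye_distance_qc needs at least two cohorts")
    means = {}
    for name, group in cohorts.items():
        if not group:
            raise InvalidParameterError(f"cohort {name!r} is empty")
        means[name] = float(
            np.mean([lm.eye_distance_px() for lm in group]) * pixel_size_um
        )
    values = np.array(list(means.values()))
    max_rel = float((values.max() - values.min()) / values.min())
    return EyeDistanceReport(
        cohort_means=means,
        max_relative_difference=max_rel,
        limit=limit,
        flagged=max_rel > limit,
    )
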