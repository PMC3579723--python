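"""In-situ expression maps in the normalized frame, and their gradients.

Staining images registered with the same eye landmarks as the axon data are
reduced to per-bin mean intensities on the analysis grid.  Replicate
hybridizations are rescaled to unit mean over the region before averaging
(absolute staining strength varies between runs even for comparably
developed stains).  The per-bin expression-gradient vectors point from high
to low label — the direction a repellent gradient pushes growth cones — with
magnitude equal to the local gradient norm in intensity per normalized unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CalibrationError, InvalidParameterError
from .image import RasterImage
from .registration import EmbryoLandmarks, GridSpec, similarity_transform


def bin_intensity(
    image: RasterImage,
    landmarks: EmbryoLandmarks,
    grid: GridSpec | None = None,
    chiasm_side: int = 1,
) -> np.ndarray:
    """Per-bin mean staining intensity of one specimen.

    Every pixel centre is mapped to (m, p); bins average the intensities of
    the pixels landing in them, NaN where none do.  Raises when the region
    catches no pixel at all (wrong landmarks or field of view).
    """
    grid = grid or GridSpec()
    tr = similarity_transform(landmarks, chiasm_side)
    yy, xx = np.indices(image.shape, dtype=float)
    m, p = tr.apply_points(xx.ravel(), yy.ravel())
    row, col, inside = grid.bin_indices(m, p)
    if not inside.any():
        raise InvalidParameterError(
            "no image pixel falls inside the analysis region; check landmarks"
        )
    flat = row[inside] * grid.n_cols + col[inside]
    nbins = grid.n_rows * grid.n_cols
    sums = np.bincount(flat, weights=image.pixels.ravel()[inside], minlength=nbins)
    counts = np.bincount(flat, minlength=nbins)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    means[counts == 0] = np.nan
    return means.reshape(grid.n_rows, grid.n_cols)


def average_expression_maps(maps: list[np.ndarray]) -> np.ndarray:
    """Mean of replicate maps after rescaling each to unit mean.

    The rescale removes between-replicate staining-strength differences;
    averaging is then element-wise, ignoring bins missing in a replicate.
    """
    if not maps:
        raise InvalidParameterError("average_expression_maps needs >= 1 map")
    shape = maps[0].shape
    rescaled = []
    for mp in maps:
        if mp.shape != shape:
            raise CalibrationError(f"grid mismatch: {mp.shape} vs {shape}")
        mean = np.nanmean(mp)
        if not (mean > 0):
            raise InvalidParameterError("expression map has non-positive mean")
        rescaled.append(mp / mean)
    return np.nanmean(np.stack(rescaled), axis=0)


def expression_gradient(
    mean_map: np.ndarray, grid: GridSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin high-to-low gradient vectors of a bin-mean intensity map.

    Central differences on the grid (one-sided at edges), with spacing equal
    to the bin widths in normalized units.  Returns ``(gm, gp)`` components
    of the *descent* direction (-grad I): the vector points from high to low
    intensity, and its norm equals the gradient magnitude.
    """
    grid = grid or GridSpec()
    if mean_map.shape != (grid.n_rows, grid.n_cols):
        raise CalibrationError(
            f"map shape {mean_map.shape} does not match grid "
            f"({grid.n_rows}, {grid.n_cols})"
        )
    if min(mean_map.shape) < 3:
        raise InvalidParameterError("gradient needs at least a 3 x 3 map")
    dp, dm = np.gradient(mean_map, grid.p_width, grid.m_width)
    return -dm, -dp


@dataclass
class OverlayReport:
    """Joint axon/expression rendering plus the per-bin angle table."""

    figure: object
    table: pd.DataFrame


def _axial_angle_to_vector(theta: np.ndarray, gm: np.ndarray, gp: np.ndarray) -> np.ndarray:
    """Acute angle (deg) between an axial orientation and a vector, per bin."""
    grad_angle = np.arctan2(gp, gm)
    diff = np.mod(theta - grad_angle, np.pi)
    return np.degrees(np.minimum(diff, np.pi - diff))


def overlay_report(
    mean_orientation: np.ndarray,
    mean_curv_direction: np.ndarray,
    mean_curv_magnitude: np.ndarray,
    gradient: tuple[np.ndarray, np.ndarray],
    expression_map: np.ndarray | None = None,
    grid: GridSpec | None = None,
) -> OverlayReport:
    """Overlay mean axon orientation, curvature and expression gradient.

    Produces one quiver figure in the normalized frame (orientation in red,
    curvature in green, expression gradient in yellow over the staining
    map) and a table with, per bin, the acute angle between the mean axon
    orientation and the expression-gradient line.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    grid = grid or GridSpec()
    gm, gp = gradient
    mc = 0.5 * (grid.m_edges[:-1] + grid.m_edges[1:])
    pc = 0.5 * (grid.p_edges[:-1] + grid.p_edges[1:])
    mm, pp = np.meshgrid(mc, pc)

    fig, ax = plt.subplots(figsize=(6, 6))
    if expression_map is not None:
        ax.imshow(
            expression_map,
            extent=(*grid.m_range, grid.p_range[1], grid.p_range[0]),
            cmap="gray",
            aspect="auto",
        )
    scale_u = 0.6 * grid.m_width
    ax.quiver(
        mm, pp, np.cos(mean_orientation) * scale_u, np.sin(mean_orientation) * scale_u,
        color="red", angles="xy", scale_units="xy", scale=1,
        headwidth=1, headlength=0, label="orientation",
    )
    mag = np.nan_to_num(mean_curv_magnitude)
    mag = mag / (np.nanmax(mag) + 1e-12) * grid.m_width
    ax.quiver(
        mm, pp, np.cos(mean_curv_direction) * mag, np.sin(mean_curv_direction) * mag,
        color="green", angles="xy", scale_units="xy", scale=1, label="curvature",
    )
    gnorm = np.hypot(gm, gp)
    gscale = grid.m_width / (np.nanmax(gnorm) + 1e-12)
    ax.quiver(
        mm, pp, gm * gscale, gp * gscale,
        color="gold", angles="xy", scale_units="xy", scale=1, label="expression gradient",
    )
    ax.set_xlabel("m (mediolateral, eyes at 0 and 1)")
    ax.set_ylabel("p (posterior)")
    ax.invert_yaxis()
    ax.legend(loc="upper right", fontsize=8)

    angle = _axial_angle_to_vector(mean_orientation, gm, gp)
    rows, cols = np.meshgrid(
        np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij"
    )
    table = pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "orientation_rad": mean_orientation.ravel(),
            "gradient_m": gm.ravel(),
            "gradient_p": gp.ravel(),
            "axon_to_gradient_deg": angle.ravel(),
        }
    )
    return OverlayReport(figure=fig, table=table)
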