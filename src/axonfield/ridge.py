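"""Reduction of the orientation field to axon centreline pixels.

Three pruning steps follow the filtering stage: non-maximum suppression
across the local ridge normal, a global median-based intensity/response
threshold, and — where the detector clipped — harmonic inpainting of
orientations over saturated patches.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from .errors import InvalidParameterError
from .filters import OrientationField
from .image import RasterImage

log = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=bool)


def _flank_responses(
    response: np.ndarray, normal: np.ndarray, mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """Responses at unit-pixel offsets along the normal on either side."""
    yy, xx = np.indices(response.shape, dtype=float)
    dx = np.cos(normal)
    dy = np.sin(normal)
    if mode == "snapped":
        dx = np.round(dx)
        dy = np.round(dy)
    elif mode != "interpolated":
        raise InvalidParameterError(f"unknown nms flank mode {mode!r}")
    f1 = ndimage.map_coordinates(
        response, [yy + dy, xx + dx], order=1, mode="nearest"
    )
    f2 = ndimage.map_coordinates(
        response, [yy - dy, xx - dx], order=1, mode="nearest"
    )
    return f1, f2


def nms_keep(
    theta: np.ndarray, response: np.ndarray, flank_mode: str = "interpolated"
) -> np.ndarray:
    """Pixels whose response strictly exceeds both flanks across the ridge.

    The flanking positions sit one pixel away along the normal to the local
    orientation (theta + pi/2); their responses are bilinearly interpolated
    (or snapped to the nearest integer offset in ``snapped`` mode).  Strict
    inequality suppresses plateaus, so a flat field keeps nothing.
    """
    f1, f2 = _flank_responses(response, theta + 0.5 * np.pi, flank_mode)
    return (response > f1) & (response > f2)


def nonmax_suppress(
    field: OrientationField, flank_mode: str = "interpolated"
) -> OrientationField:
    """Thin the mask to ridge centrelines (mask-only change)."""
    out = field.copy()
    out.mask &= nms_keep(field.theta, field.response, flank_mode)
    return out


def median_threshold(
    image: RasterImage, field: OrientationField, factor: float = 2.0
) -> OrientationField:
    """Drop pixels dimmer or weaker-responding than ``factor`` x the median.

    Both medians are taken over *all* pixels of the image (not only masked
    ones); a pixel survives only if intensity >= factor * median(intensity)
    and response >= factor * median(response).
    """
    if not (factor > 0):
        raise InvalidParameterError(f"factor must be > 0, got {factor}")
    med_int = float(np.median(image.pixels))
    med_resp = float(np.median(field.response))
    out = field.copy()
    out.mask &= image.pixels >= factor * med_int
    out.mask &= field.response >= factor * med_resp
    return out


def detect_saturation(image: RasterImage) -> np.ndarray:
    """Boolean raster of clipped pixels (intensity >= saturation level)."""
    if image.saturation_level is None:
        log.warning("no saturation level set; assuming no clipped pixels")
        return np.zeros(image.shape, dtype=bool)
    return image.pixels >= image.saturation_level


def _laplace_inpaint(
    comp: np.ndarray, boundary_value: np.ndarray, boundary_mask: np.ndarray
) -> np.ndarray:
    """Solve the Laplace equation on ``comp`` with Dirichlet rim values.

    Interior pixels neighbouring neither an unknown nor a boundary pixel
    (e.g. at the image border) get a natural (no-flux) treatment by simply
    dropping that neighbour from the stencil.
    """
    idx = -np.ones(comp.shape, dtype=int)
    ys, xs = np.nonzero(comp)
    idx[ys, xs] = np.arange(len(ys))
    n = len(ys)
    rows, cols, vals = [], [], []
    rhs = np.zeros(n)
    h, w = comp.shape
    for k, (y, x) in enumerate(zip(ys, xs)):
        degree = 0
        for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ny, nx = y + dy, x + dx
            if not (0 <= ny < h and 0 <= nx < w):
                continue
            if comp[ny, nx]:
                rows.append(k)
                cols.append(idx[ny, nx])
                vals.append(-1.0)
                degree += 1
            elif boundary_mask[ny, nx]:
                rhs[k] += boundary_value[ny, nx]
                degree += 1
        rows.append(k)
        cols.append(k)
        vals.append(float(degree) if degree > 0 else 1.0)
    mat = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    sol = spsolve(mat.tocsc(), rhs)
    out = np.zeros(comp.shape)
    out[ys, xs] = sol
    return out


def interpolate_saturated(
    field: OrientationField, sat_mask: np.ndarray
) -> OrientationField:
    """Fill orientations inside saturated patches from their rims.

    Orientations are axial, so the interpolation runs in doubled-angle
    space: cos(2 theta) and sin(2 theta) are each harmonically (Laplace)
    interpolated with Dirichlet values taken from the one-pixel rim of the
    patch, then recombined with atan2.  The response inside is set to the
    rim's mean response and the patch pixels are restored to the mask.
    Patches with no valid rim (e.g. clipped regions running off the image)
    are left masked out.
    """
    if sat_mask.shape != field.theta.shape:
        raise InvalidParameterError("saturation mask shape mismatch")
    out = field.copy()
    if not sat_mask.any():
        return out
    labels, n_comp = ndimage.label(sat_mask, structure=_EIGHT)
    cos2 = np.cos(2.0 * field.theta)
    sin2 = np.sin(2.0 * field.theta)
    for comp_id in range(1, n_comp + 1):
        comp = labels == comp_id
        rim = ndimage.binary_dilation(comp, structure=_EIGHT) & ~comp & field.mask
        if not rim.any():
            log.warning(
                "saturated component %d has no valid rim; leaving it masked out",
                comp_id,
            )
            continue
        c_fill = _laplace_inpaint(comp, cos2, rim)
        s_fill = _laplace_inpaint(comp, sin2, rim)
        theta_fill = np.mod(0.5 * np.arctan2(s_fill, c_fill), np.pi)
        out.theta[comp] = theta_fill[comp]
        out.response[comp] = field.response[rim].mean()
        out.mask[comp] = True
    return out
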