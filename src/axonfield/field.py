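r"""Direction fields and curl-derived curvature.

Orientations from the filter stage are axial (defined modulo pi).  To turn
them into directions of travel, each retained pixel takes the one of its two
candidate directions that points *away from the injected eye* — the sense in
which labelled axons actually grow.  The direction field is then smoothed
with a wide Gaussian (normalized convolution restricted to retained pixels)
and differentiated: for a unit vector field :math:`v = (\cos d, \sin d)` the
2-D scalar curl

.. math:: \operatorname{curl} v = \partial_x v_y - \partial_y v_x

equals the rate of turning of the angle along the flow, i.e. the local
trajectory curvature in rad per unit length.  The curvature "vector" points
along the turn-side normal with length :math:`|\kappa|`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError
from .filters import OrientationField
from .ridge import nms_keep

log = logging.getLogger(__name__)


@dataclass
class DirectionField:
    """Per-pixel direction of travel (radians in [0, 2 pi)).

    ``mask`` marks retained centreline pixels.  ``support`` marks where the
    direction value itself is meaningful — after smoothing this extends into
    a band around the centrelines, which is what makes finite differences
    well defined at the mask.
    """

    direction: np.ndarray
    mask: np.ndarray
    support: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.support is None:
            self.support = self.mask.copy()


@dataclass
class CurvatureField:
    """Signed scalar curvature and the derived curvature vector.

    ``kappa`` is in rad/um, positive for turns toward the +pi/2 normal of
    the travel direction.  The curvature vector has magnitude ``|kappa|``
    and direction ``curvature_angle`` (the turn-side normal), perpendicular
    to the travel direction wherever defined.
    """

    kappa: np.ndarray
    curvature_angle: np.ndarray
    mask: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.kappa)


def to_direction_field(
    field: OrientationField, injection_point: tuple[float, float]
) -> DirectionField:
    """Disambiguate each orientation into a direction away from the eye.

    For a pixel p with orientation theta the candidates are theta and
    theta + pi; the one with positive dot product with (p - injection_point)
    wins.  When that dot product vanishes (pixel on the line through the
    injection point orthogonal to the orientation, or coincident with it)
    the tie-break keeps the candidate with positive x-component, falling
    back to positive y for vertical orientations.
    """
    ix, iy = injection_point
    yy, xx = np.indices(field.theta.shape, dtype=float)
    rx = xx - ix
    ry = yy - iy
    c = np.cos(field.theta)
    s = np.sin(field.theta)
    dot = c * rx + s * ry
    direction = np.where(dot >= 0, field.theta, field.theta + np.pi)
    # ties: positive-x candidate; theta in [0, pi) has cos > 0 iff theta < pi/2,
    # and at theta = pi/2 the +y candidate is theta itself
    tie = dot == 0
    if np.any(tie):
        flip = tie & (field.theta > 0.5 * np.pi)
        direction = np.where(flip, field.theta + np.pi, direction)
        direction = np.where(tie & ~flip, field.theta, direction)
    return DirectionField(direction=np.mod(direction, 2.0 * np.pi), mask=field.mask.copy())


def resolve_directions(
    field: OrientationField, reference_direction: np.ndarray
) -> DirectionField:
    """Disambiguate orientations against an externally supplied sense.

    Picks, per pixel, the candidate in {theta, theta + pi} within a quarter
    turn of ``reference_direction`` (e.g. a known travel direction from a
    phantom generator, or a prior flow estimate).  The eye-based rule in
    :func:`to_direction_field` is the pipeline default; this primitive
    serves geometries where a radial sense is ill-posed, such as closed
    test loops.
    """
    delta = np.mod(reference_direction - field.theta + np.pi, 2.0 * np.pi) - np.pi
    flip = np.abs(delta) > 0.5 * np.pi
    direction = np.mod(field.theta + np.where(flip, np.pi, 0.0), 2.0 * np.pi)
    return DirectionField(direction=direction, mask=field.mask.copy())


def smooth_direction_field(
    dir_field: DirectionField,
    sigma_um: float = 30.0,
    pixel_size_um: float = 1.0,
    support_eps: float = 1e-6,
) -> DirectionField:
    """Gaussian-smooth the direction field by normalized convolution.

    The unit-vector components, zeroed off the mask, are blurred together
    with the mask indicator; the smoothed direction is the atan2 of the
    mask-normalised components, so off-axon zeros never bias the angle and a
    uniform field passes through unchanged.  The retained-pixel mask is not
    modified, but the field's ``support`` widens to everywhere the blurred
    indicator is appreciable, giving downstream derivatives room to work.
    """
    if not (sigma_um > 0):
        raise InvalidParameterError(f"sigma_um must be > 0, got {sigma_um}")
    if not dir_field.mask.any():
        log.warning("direction field mask is empty; smoothing skipped")
        return DirectionField(
            dir_field.direction.copy(), dir_field.mask.copy(), dir_field.support.copy()
        )
    sigma_px = sigma_um / pixel_size_um
    w = dir_field.mask.astype(float)
    cx = ndimage.gaussian_filter(w * np.cos(dir_field.direction), sigma_px)
    sx = ndimage.gaussian_filter(w * np.sin(dir_field.direction), sigma_px)
    ww = ndimage.gaussian_filter(w, sigma_px)
    support = ww > support_eps
    direction = dir_field.direction.copy()
    direction[support] = np.mod(
        np.arctan2(sx[support], cx[support]), 2.0 * np.pi
    )
    return DirectionField(direction=direction, mask=dir_field.mask.copy(), support=support)


def _masked_derivative(values: np.ndarray, valid: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Central differences falling back to one-sided where support ends.

    Returns (derivative in units of 1/px, defined-mask).
    """
    fwd = np.roll(values, -1, axis=axis)
    bwd = np.roll(values, 1, axis=axis)
    v_fwd = np.roll(valid, -1, axis=axis)
    v_bwd = np.roll(valid, 1, axis=axis)
    # rolled-in wrap values are invalid at the array edges
    edge_lo = [slice(None)] * values.ndim
    edge_hi = [slice(None)] * values.ndim
    edge_lo[axis] = 0
    edge_hi[axis] = -1
    v_bwd[tuple(edge_lo)] = False
    v_fwd[tuple(edge_hi)] = False
    both = v_fwd & v_bwd
    only_f = v_fwd & ~v_bwd
    only_b = v_bwd & ~v_fwd
    deriv = np.zeros_like(values)
    deriv[both] = 0.5 * (fwd[both] - bwd[both])
    deriv[only_f] = fwd[only_f] - values[only_f]
    deriv[only_b] = values[only_b] - bwd[only_b]
    return deriv, (both | only_f | only_b) & valid


def curvature_from_curl(
    dir_field: DirectionField, pixel_size_um: float
) -> CurvatureField:
    """Signed trajectory curvature from the curl of the unit direction field.

    Derivatives are central differences over the field's support (one-sided
    at support edges); pixels with no usable neighbour along either axis are
    dropped from the mask.  The result is expressed in rad/um.
    """
    if not (pixel_size_um > 0):
        raise InvalidParameterError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    valid = dir_field.support
    vx = np.where(valid, np.cos(dir_field.direction), 0.0)
    vy = np.where(valid, np.sin(dir_field.direction), 0.0)
    dvy_dx, ok_x = _masked_derivative(vy, valid, axis=1)
    dvx_dy, ok_y = _masked_derivative(vx, valid, axis=0)
    kappa = (dvy_dx - dvx_dy) / pixel_size_um
    defined = ok_x & ok_y
    mask = dir_field.mask & defined
    curvature_angle = np.mod(
        dir_field.direction + np.sign(kappa) * 0.5 * np.pi, 2.0 * np.pi
    )
    kappa = np.where(defined, kappa, np.nan)
    return CurvatureField(kappa=kappa, curvature_angle=curvature_angle, mask=mask)


def second_nonmax(
    dir_field: DirectionField,
    response: np.ndarray,
    flank_mode: str = "interpolated",
) -> np.ndarray:
    """Re-run non-maximum suppression with smoothed normals.

    Smoothing can drag orientations slightly off the original centrelines;
    suppressing again — with the normal defined by the *smoothed* direction
    (mod pi) and the original filter response — prunes pixels that are no
    longer local maxima across their corrected normal.  Returns the updated
    retained mask.
    """
    theta = np.mod(dir_field.direction, np.pi)
    return dir_field.mask & nms_keep(theta, response, flank_mode)
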