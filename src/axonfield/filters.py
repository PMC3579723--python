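r"""Steerable second-derivative Gaussian (G2) filtering.

Bright axons appear as ridges of roughly Gaussian cross-section.  The matched
ridge detector at orientation :math:`\theta` is the *negated* second
directional derivative of a Gaussian taken along the ridge normal
:math:`n(\theta) = (-\sin\theta, \cos\theta)`: it responds maximally, and
positively, when the filter orientation runs along a bright ridge.

That detector is steerable with a three-member basis.  Writing
:math:`G_{xx}, G_{xy}, G_{yy}` for the second partial derivatives of the
Gaussian, the basis kernels used here are

.. math::

    k_a = -\sigma^2 G_{yy}, \qquad
    k_b = -\sigma^2 G_{xy}, \qquad
    k_c = -\sigma^2 G_{xx},

(the :math:`\sigma^2` factor makes responses scale-free) and the exact
steering identity is

.. math::

    R(\theta) = \cos^2\theta\, r_a - 2\cos\theta\sin\theta\, r_b
                + \sin^2\theta\, r_c ,

where :math:`r_{a,b,c}` are the image responses to the three kernels.
:math:`R(\theta)` is a second-harmonic trigonometric polynomial,
:math:`R = A + B\cos 2\theta + C\sin 2\theta` with
:math:`A = (r_a + r_c)/2`, :math:`B = (r_a - r_c)/2`, :math:`C = -r_b`,
so the orientation of maximum response has the closed form
:math:`\theta^* = \tfrac12\,\mathrm{atan2}(C, B)` with peak response
:math:`A + \sqrt{B^2 + C^2}`.

Angles follow the image convention: radians, measured from the +x (column)
axis toward +y (row, downward).  Orientations are axial (defined modulo
:math:`\pi`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import CalibrationError, InvalidParameterError, UndersamplingError
from .image import RasterImage

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class FilterBank:
    """Sampled G2 basis kernels at one physical scale.

    ``kernel_a`` detects ridges along x (theta = 0), ``kernel_c`` is its
    90-degree rotation (ridges along y) and ``kernel_b`` is the mixed term
    that steers between them.  Each kernel sums to zero so constant images
    give zero response.
    """

    sigma_um: float
    pixel_size_um: float
    kernel_a: np.ndarray
    kernel_b: np.ndarray
    kernel_c: np.ndarray
    support_radius_px: int

    @property
    def sigma_px(self) -> float:
        return self.sigma_um / self.pixel_size_um


@dataclass
class BasisResponses:
    """Responses of one image to the three basis kernels (same shape each)."""

    r_a: np.ndarray
    r_b: np.ndarray
    r_c: np.ndarray
    support_radius_px: int


@dataclass
class OrientationField:
    """Per-pixel best ridge orientation and its steered response.

    ``theta`` is axial, in [0, pi).  ``mask`` marks pixels still considered
    to lie on an axon; it starts true everywhere except a border band one
    kernel support wide (border responses are contaminated by padding) and
    is only ever pruned by downstream steps.
    """

    theta: np.ndarray
    response: np.ndarray
    mask: np.ndarray

    def copy(self) -> "OrientationField":
        return OrientationField(
            self.theta.copy(), self.response.copy(), self.mask.copy()
        )


def _gaussian_second_derivatives(
    sigma_px: float, radius: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    offsets = np.arange(-radius, radius + 1, dtype=float)
    x, y = np.meshgrid(offsets, offsets)  # x varies along columns
    g = np.exp(-(x**2 + y**2) / (2.0 * sigma_px**2)) / (2.0 * np.pi * sigma_px**2)
    s2 = sigma_px**2
    gxx = (x**2 / s2 - 1.0) / s2 * g
    gyy = (y**2 / s2 - 1.0) / s2 * g
    gxy = (x * y) / (s2 * s2) * g
    return gxx, gxy, gyy


def build_filter_bank(
    sigma_um: float,
    pixel_size_um: float,
    *,
    sigma_is_fwhm: bool = False,
    truncate_sigmas: float = 4.0,
) -> FilterBank:
    """Sample the G2 basis at the image pixel pitch.

    ``sigma_um`` is the Gaussian scale of the filters (1.8 um matches the
    calibre of embryonic axon bundles).  Set ``sigma_is_fwhm`` to interpret
    the width as full width at half maximum instead.  Kernels are truncated
    at ``truncate_sigmas`` * sigma and the (tiny) truncation residual of the
    even kernels is removed by mean subtraction so every kernel sums to zero.
    """
    if not (sigma_um > 0):
        raise InvalidParameterError(f"sigma_um must be > 0, got {sigma_um}")
    if not (pixel_size_um > 0):
        raise InvalidParameterError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    if sigma_is_fwhm:
        sigma_um = sigma_um / FWHM_PER_SIGMA
    sigma_px = sigma_um / pixel_size_um
    if sigma_px < 0.5:
        raise UndersamplingError(
            f"filter sigma is {sigma_px:.3f} px (< 0.5 px); the image pixel "
            "pitch is too coarse for this filter scale"
        )
    radius = int(math.ceil(truncate_sigmas * sigma_px))
    gxx, gxy, gyy = _gaussian_second_derivatives(sigma_px, radius)
    s2 = sigma_px**2
    kernel_a = -s2 * gyy
    kernel_b = -s2 * gxy
    # gxy is odd in x and in y, so it sums to zero exactly on the symmetric
    # grid; the even kernels carry a truncation residual that is spread
    # uniformly over the support.
    kernel_a = kernel_a - kernel_a.sum() / kernel_a.size
    # -s2 * gxx equals the 90-degree rotation of kernel_a on the symmetric
    # grid; taking it literally as the rotated array makes the identity exact
    kernel_c = np.ascontiguousarray(np.rot90(kernel_a))
    return FilterBank(
        sigma_um=sigma_um,
        pixel_size_um=pixel_size_um,
        kernel_a=kernel_a,
        kernel_b=kernel_b,
        kernel_c=kernel_c,
        support_radius_px=radius,
    )


def oriented_kernel(bank: FilterBank, theta: float) -> np.ndarray:
    """Sample the rotated ridge detector at ``theta`` directly.

    This bypasses steering: the analytic kernel expression is rotated and
    re-sampled, which is useful as an independent check of the steering
    identity.
    """
    radius = bank.support_radius_px
    sigma_px = bank.sigma_px
    offsets = np.arange(-radius, radius + 1, dtype=float)
    x, y = np.meshgrid(offsets, offsets)
    # coordinates in the frame rotated by -theta
    yr = -x * math.sin(theta) + y * math.cos(theta)
    g = np.exp(-(x**2 + y**2) / (2.0 * sigma_px**2)) / (2.0 * np.pi * sigma_px**2)
    s2 = sigma_px**2
    kern = -s2 * (yr**2 / s2 - 1.0) / s2 * g
    return kern - kern.sum() / kern.size


def basis_responses(image: RasterImage, bank: FilterBank) -> BasisResponses:
    """Convolve the image with the three basis kernels (reflect padding)."""
    if not math.isclose(image.pixel_size_um, bank.pixel_size_um, rel_tol=1e-9):
        raise CalibrationError(
            f"image pixel pitch {image.pixel_size_um} um does not match "
            f"filter bank pitch {bank.pixel_size_um} um"
        )
    # all three kernels are even under point reflection, so convolution and
    # correlation coincide; FFT convolution on a reflect-padded frame
    r = bank.support_radius_px
    # "symmetric" repeats the edge sample, matching scipy.ndimage's
    # reflect-boundary convention
    padded = np.pad(image.pixels, r, mode="symmetric")
    crop = (slice(r, -r), slice(r, -r)) if r > 0 else (slice(None), slice(None))
    responses = [
        signal.fftconvolve(padded, k, mode="same")[crop]
        for k in (bank.kernel_a, bank.kernel_b, bank.kernel_c)
    ]
    return BasisResponses(*responses, bank.support_radius_px)


def steered_response(basis: BasisResponses, theta: float) -> np.ndarray:
    """Response of the ridge detector steered to ``theta``, via the basis."""
    if not np.isfinite(theta):
        raise InvalidParameterError("theta must be finite")
    c, s = math.cos(theta), math.sin(theta)
    return c * c * basis.r_a - 2.0 * c * s * basis.r_b + s * s * basis.r_c


def dominant_orientation(basis: BasisResponses) -> OrientationField:
    """Closed-form orientation of maximum steered response at every pixel.

    Isotropic pixels (B = C = 0, response independent of angle) get
    theta = 0 by the atan2 convention; they carry no orientation information
    and are removed later by non-maximum suppression.
    """
    a = 0.5 * (basis.r_a + basis.r_c)
    b = 0.5 * (basis.r_a - basis.r_c)
    c = -basis.r_b
    theta = 0.5 * np.arctan2(c, b)
    theta = np.mod(theta, np.pi)
    response = a + np.hypot(b, c)
    mask = np.ones(theta.shape, dtype=bool)
    r = basis.support_radius_px
    if r > 0:
        mask[:r, :] = False
        mask[-r:, :] = False
        mask[:, :r] = False
        mask[:, -r:] = False
    return OrientationField(theta=theta, response=response, mask=mask)
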