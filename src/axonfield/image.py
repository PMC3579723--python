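"""Calibrated 2-D intensity rasters.

A :class:`RasterImage` couples a non-negative 2-D intensity array with the
physical pixel pitch in micrometres and, optionally, the intensity level at
which the detector clips.  All image-domain operations in the package consume
this type, so physical scales (filter width, smoothing length) can always be
converted to pixels.

Array convention: ``pixels[row, col]`` with row = y (downward) and
col = x (rightward).  Point coordinates are ``(x, y)`` floats in pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InputFormatError, InvalidParameterError


@dataclass
class RasterImage:
    """A single-channel fluorescence image with physical calibration.

    Parameters
    ----------
    pixels
        2-D array of finite, non-negative intensities.
    pixel_size_um
        Physical size of one pixel in micrometres (> 0).
    saturation_level
        Intensity at which the detector clips, if known.  Saturation
        handling is skipped when it is ``None``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    saturation_level: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise InvalidParameterError(
                f"expected a 2-D raster, got shape {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidParameterError("image contains non-finite intensities")
        if np.any(self.pixels < 0):
            raise InvalidParameterError("image contains negative intensities")
        if not (self.pixel_size_um > 0):
            raise InvalidParameterError(
                f"pixel_size_um must be > 0, got {self.pixel_size_um}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def load_image(
    path: str | Path,
    pixel_size_um: float,
    saturation_level: float | None = None,
    channel: int | None = None,
) -> RasterImage:
    """Read a TIFF or PNG file into a :class:`RasterImage`.

    Multi-channel input raises :class:`InputFormatError` unless ``channel``
    selects one plane.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        data = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        data = iio.imread(path)
    data = np.asarray(data)
    if data.ndim == 3:
        if channel is None:
            raise InputFormatError(
                f"{path}: image has {data.shape} channels/planes; "
                "pass a channel index to select one"
            )
        # channel axis is whichever axis is small (planar TIFF vs interleaved PNG)
        axis = int(np.argmin(data.shape))
        data = np.take(data, channel, axis=axis)
    elif data.ndim != 2:
        raise InputFormatError(f"{path}: unsupported image dimensionality {data.ndim}")
    return RasterImage(data.astype(float), pixel_size_um, saturation_level)


def save_image(image: RasterImage, path: str | Path) -> None:
    """Write a raster to TIFF (float32) or PNG (rescaled to 8 bit)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, image.pixels.astype(np.float32))
    else:
        import imageio.v3 as iio

        arr = image.pixels
        top = arr.max() if arr.max() > 0 else 1.0
        iio.imwrite(path, np.clip(arr / top * 255, 0, 255).astype(np.uint8))
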