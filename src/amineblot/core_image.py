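"""Image containers and the weighted-intensity arithmetic used throughout.

All grayscale values in this package are the weighted channel sum
``0.30 R + 0.59 G + 0.11 B`` carried as real numbers in [0, 255];
quantization to 8-bit happens only at export, with round-half-away-from-zero.
Coordinates are 0-based, row-major, origin at the top-left.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import DataError, ShapeError

#: Channel weights for grayscale conversion (red, green, blue). They sum to 1.
GRAY_WEIGHTS: tuple[float, float, float] = (0.30, 0.59, 0.11)


@dataclass(frozen=True)
class RGBImage:
    """An 8-bit three-channel image, shape (height, width, 3), dtype uint8."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ShapeError(f"RGBImage requires shape (H, W, 3), got {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise DataError("RGBImage channels must be integers")
        if arr.size and (arr.min() < 0 or arr.max() > 255):
            raise DataError("RGBImage channel values must lie in [0, 255]")
        object.__setattr__(self, "pixels", arr.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GrayImage:
    """A real-valued single-channel image with intensities in [0.0, 255.0]."""

    intensity: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=np.float64)
        if arr.ndim != 2:
            raise ShapeError(f"GrayImage requires shape (H, W), got {arr.shape}")
        if arr.size and (arr.min() < 0.0 or arr.max() > 255.0):
            raise DataError("GrayImage intensities must lie in [0.0, 255.0]")
        object.__setattr__(self, "intensity", arr)

    @property
    def height(self) -> int:
        return self.intensity.shape[0]

    @property
    def width(self) -> int:
        return self.intensity.shape[1]


def weighted_intensity(r: float, g: float, b: float) -> float:
    """Weighted sum of the red, green and blue channels.

    Parameters
    ----------
    r, g, b : float
        Channel values, each in [0, 255].

    Returns
    -------
    float
        ``0.30*r + 0.59*g + 0.11*b``, a real number in [0, 255].
    """
    for name, v in (("r", r), ("g", g), ("b", b)):
        if not 0 <= v <= 255:
            raise DataError(f"channel {name}={v} outside [0, 255]")
    wr, wg, wb = GRAY_WEIGHTS
    return wr * r + wg * g + wb * b


def to_gray(image: RGBImage) -> GrayImage:
    """Convert an RGB image to grayscale with the weighted channel sum."""
    wr, wg, wb = GRAY_WEIGHTS
    arr = image.pixels.astype(np.float64)
    return GrayImage(arr[..., 0] * wr + arr[..., 1] * wg + arr[..., 2] * wb)


def round_half_away(values: np.ndarray | float) -> np.ndarray | float:
    """Round half away from zero (the package-wide export rounding rule)."""
    arr = np.asarray(values, dtype=np.float64)
    out = np.sign(arr) * np.floor(np.abs(arr) + 0.5)
    return float(out) if np.isscalar(values) else out


def multiply_blend(base: RGBImage | GrayImage, layer: RGBImage) -> RGBImage:
    """Multiply-blend ``layer`` onto ``base``: per channel round(b*l/255).

    A gray base is broadcast to three channels first. The operation is
    symmetric in its arguments and never brightens: every output channel
    is bounded by min(base, layer) up to rounding slack.
    """
    if isinstance(base, GrayImage):
        base_arr = np.repeat(base.intensity[:, :, None], 3, axis=2)
    else:
        base_arr = base.pixels.astype(np.float64)
    layer_arr = layer.pixels.astype(np.float64)
    if base_arr.shape != layer_arr.shape:
        raise ShapeError(
            f"multiply_blend dimension mismatch: {base_arr.shape[:2]} vs {layer_arr.shape[:2]}"
        )
    out = round_half_away(base_arr * layer_arr / 255.0)
    return RGBImage(np.clip(out, 0, 255))


def gray_to_rgb(image: GrayImage) -> RGBImage:
    """Quantize a gray image (round-half-away) and broadcast it to 3 channels."""
    q = np.clip(round_half_away(image.intensity), 0, 255)
    return RGBImage(np.repeat(q[:, :, None], 3, axis=2))


def read_image(path: str | Path) -> RGBImage:
    """Read an 8-bit PNG/TIFF as an RGBImage. Alpha channels are rejected."""
    with Image.open(path) as im:
        if im.mode in ("RGBA", "LA", "PA"):
            raise DataError(
                f"{path}: alpha channel not supported; flatten the image first"
            )
        if im.mode not in ("RGB", "L", "P", "I;16", "I"):
            raise DataError(f"{path}: unsupported image mode {im.mode!r}")
        rgb = im.convert("RGB")
        arr = np.asarray(rgb, dtype=np.uint8)
    return RGBImage(arr)


def write_image(image: RGBImage | GrayImage, path: str | Path) -> None:
    """Write an image as 8-bit PNG or TIFF (inferred from the suffix)."""
    if isinstance(image, GrayImage):
        image = gray_to_rgb(image)
    Image.fromarray(image.pixels, mode="RGB").save(path)
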