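"""Concentration heatmaps on a standardized color scale, and root/blot
overlay composites.

Registration between root scan and blot is manual (user-supplied offset and
rotation); the blot layer is resampled nearest-neighbor so no intensities
are invented before blending.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib
import numpy as np

from .calibration import CalibrationModel, intensity_to_conc
from .core_image import GrayImage, RGBImage, round_half_away, to_gray
from .errors import AlignmentError, DataError

DEFAULT_COLORMAP = "viridis"


@dataclass(frozen=True)
class ColorScale:
    """Concentration-to-color mapping with ordered stops and scale bounds."""

    min_conc: float = 0.0
    max_conc: float = 4.71
    colormap: str = DEFAULT_COLORMAP
    n_stops: int = 256
    legend: bool = True

    def __post_init__(self) -> None:
        if not self.min_conc < self.max_conc:
            raise DataError("ColorScale requires min_conc < max_conc")
        if self.n_stops < 2:
            raise DataError("ColorScale requires at least 2 stops")

    def stops(self) -> np.ndarray:
        """(n_stops, 3) uint8 colors, ordered from min_conc to max_conc."""
        cmap = matplotlib.colormaps[self.colormap]
        pos = np.linspace(0.0, 1.0, self.n_stops)
        rgba = cmap(pos)
        return np.asarray(round_half_away(rgba[:, :3] * 255.0), dtype=np.uint8)


@dataclass(frozen=True)
class ConcentrationMap:
    """Per-pixel estimated concentrations plus the rendered false-color image."""

    concentration: np.ndarray  # (H, W) float, mM, within scale bounds
    provenance: str  # identifier of the calibration model used
    rendering: RGBImage


def _model_id(model: CalibrationModel) -> str:
    return (
        f"slope={model.slope:.6g},intercept={model.intercept:.6g},"
        f"n={model.n},level={model.level}"
    )


def concentration_map(
    image: GrayImage, model: CalibrationModel, scale: ColorScale | None = None
) -> ConcentrationMap:
    """Convert every pixel's intensity to a concentration and render it."""
    scale = scale or ColorScale(max_conc=model.clamp_max or 4.71)
    conc = intensity_to_conc(model, image.intensity)
    conc = np.clip(conc, scale.min_conc, scale.max_conc)
    return ConcentrationMap(
        concentration=conc,
        provenance=_model_id(model),
        rendering=render_heatmap_array(conc, scale),
    )


def render_heatmap_array(
    conc: np.ndarray,
    scale: ColorScale,
    tick_concs: Sequence[float] = (),
) -> RGBImage:
    """Render a concentration array through the color scale.

    Deterministic pure function. When ``scale.legend`` is set, a vertical
    gradient strip (max at top) is appended on the right with 1-px black
    tick lines at ``tick_concs``; numeric labels belong in the sidecar JSON.
    """
    stops = scale.stops()
    pos = (np.clip(conc, scale.min_conc, scale.max_conc) - scale.min_conc) / (
        scale.max_conc - scale.min_conc
    )
    idx = np.asarray(round_half_away(pos * (scale.n_stops - 1)), dtype=np.intp)
    body = stops[idx]
    if not scale.legend:
        return RGBImage(body)

    h, w = conc.shape
    strip_w = max(8, w // 20)
    frac = np.linspace(1.0, 0.0, h)  # top row = max_conc
    strip_idx = np.asarray(round_half_away(frac * (scale.n_stops - 1)), dtype=np.intp)
    strip = np.repeat(stops[strip_idx][:, None, :], strip_w, axis=1)
    for c in tick_concs:
        f = (c - scale.min_conc) / (scale.max_conc - scale.min_conc)
        if 0.0 <= f <= 1.0:
            row = int(round_half_away((1.0 - f) * (h - 1)))
            strip[row, :, :] = 0
    gap = np.full((h, 2, 3), 255, dtype=np.uint8)
    return RGBImage(np.concatenate([body, gap, strip], axis=1))


def render_heatmap(
    cmap: ConcentrationMap, scale: ColorScale, tick_concs: Sequence[float] = ()
) -> RGBImage:
    """Render an existing ConcentrationMap through ``scale``."""
    return render_heatmap_array(cmap.concentration, scale, tick_concs)


def decode_heatmap(image: RGBImage, scale: ColorScale) -> np.ndarray:
    """Nearest-stop inverse of render_heatmap (test/diagnostic helper).

    Only meaningful on legend-free renderings; returns concentrations on the
    scale's stop grid.
    """
    stops = scale.stops().astype(np.int64)
    px = image.pixels.astype(np.int64)
    d2 = ((px[:, :, None, :] - stops[None, None, :, :]) ** 2).sum(axis=-1)
    idx = d2.argmin(axis=-1)
    return scale.min_conc + idx / (scale.n_stops - 1) * (scale.max_conc - scale.min_conc)


def overlay(
    root: RGBImage,
    blot: RGBImage,
    offset: tuple[float, float] = (0.0, 0.0),
    rotation: float = 0.0,
) -> RGBImage:
    """Multiply-blend the blot onto the desaturated root scan.

    The blot is rotated ``rotation`` degrees counterclockwise about its own
    center, its center is then placed at the root image's center displaced
    by ``offset`` (rows, cols), and it is resampled nearest-neighbor.
    Output pixels outside the transformed blot keep the grayscale root.
    """
    gray = to_gray(root)
    base = np.repeat(np.asarray(round_half_away(gray.intensity))[:, :, None], 3, axis=2)

    theta = np.deg2rad(rotation)
    # forward transform in (row, col) space: rows grow downward, so a
    # display-CCW rotation by theta is [[cos, -sin], [sin, cos]]
    fwd = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    inv = fwd.T  # rotations are orthogonal
    c_out = np.array([(root.height - 1) / 2.0, (root.width - 1) / 2.0])
    c_blot = np.array([(blot.height - 1) / 2.0, (blot.width - 1) / 2.0])

    rr, cc = np.meshgrid(
        np.arange(root.height), np.arange(root.width), indexing="ij"
    )
    rel = np.stack([rr - c_out[0] - offset[0], cc - c_out[1] - offset[1]], axis=-1)
    src = rel @ inv.T + c_blot
    sr = np.asarray(round_half_away(src[..., 0]), dtype=np.intp)
    sc = np.asarray(round_half_away(src[..., 1]), dtype=np.intp)
    valid = (sr >= 0) & (sr < blot.height) & (sc >= 0) & (sc < blot.width)
    if not valid.any():
        raise AlignmentError("transform leaves no overlap between root and blot")

    out = base.astype(np.float64)
    layer = blot.pixels[sr[valid], sc[valid]].astype(np.float64)
    blended = round_half_away(out[valid] * layer / 255.0)
    out[valid] = blended
    return RGBImage(np.clip(out, 0, 255))


def write_sidecar(
    path: str | Path,
    scale: ColorScale,
    model: CalibrationModel | None = None,
    transform: dict | None = None,
    tick_concs: Sequence[float] = (),
) -> None:
    """Write the JSON sidecar documenting a rendering's scale and provenance."""
    payload = {
        "scale": {
            "min_conc_mM": scale.min_conc,
            "max_conc_mM": scale.max_conc,
            "colormap": scale.colormap,
            "n_stops": scale.n_stops,
            "legend": scale.legend,
            "legend_tick_concs_mM": list(tick_concs),
        },
        "calibration_model": model.to_dict() if model else None,
        "transform": transform,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
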