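"""Ground-truthed synthetic fixtures: calibration-spot batches, blot-paper
images, and partner root scans.

Every generator is a pure function of its parameters and seed. The gray
contract is exact by construction: blot pixels are encoded so that the
integer channel triple satisfies ``30R + 59G + 11B = round(100 * target)``,
i.e. the weighted intensity 0.30R+0.59G+0.11B matches the target gray value
to within 0.005 units. Purple tint is then added with the zero-weight
integer move (dR, dG, dB) = (+1, -2, +8), which leaves the weighted sum
unchanged (30*1 - 59*2 + 11*8 = 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core_image import RGBImage
from .errors import DataError, LayoutError
from .spot_analysis import GridSpec

#: Default generating line and standards, matching the published calibration.
DEFAULT_SLOPE = -20.98
DEFAULT_INTERCEPT = 241.71
DEFAULT_STANDARDS = (1.71, 3.41, 4.71)


@dataclass(frozen=True)
class OutlierSpec:
    """Designates one paper as an outlier at one concentration."""

    paper_id: str
    concentration: float
    shift: float = 60.0
    n_spots: int = 2


@dataclass(frozen=True)
class FixtureTruth:
    """Everything needed to verify downstream recovery of a fixture."""

    slope: float
    intercept: float
    standards: tuple
    noise_sd: float
    seed: int
    spot_concentrations: dict = field(default_factory=dict)  # cell/key -> mM
    spot_intensities: dict = field(default_factory=dict)  # cell/key -> target gray
    disk_centers: tuple = ()  # ((row, col), ...) row-major
    disk_radius: float = 0.0
    trace_points: tuple = ()  # polyline of the root band
    trace_profile: tuple = ()  # per-vertex concentration (mM)
    outliers: tuple = ()

    def to_json(self, path: str | Path) -> None:
        d = {
            "slope": self.slope,
            "intercept": self.intercept,
            "standards": list(self.standards),
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "spot_concentrations": {str(k): v for k, v in self.spot_concentrations.items()},
            "spot_intensities": {str(k): v for k, v in self.spot_intensities.items()},
            "disk_centers": [list(c) for c in self.disk_centers],
            "disk_radius": self.disk_radius,
            "trace_points": [list(p) for p in self.trace_points],
            "trace_profile": list(self.trace_profile),
            "outliers": [
                {
                    "paper_id": o.paper_id,
                    "concentration": o.concentration,
                    "shift": o.shift,
                    "n_spots": o.n_spots,
                }
                for o in self.outliers
            ],
        }
        Path(path).write_text(json.dumps(d, indent=2))


# ---------------------------------------------------------------------------
# Exact purple encoding

@lru_cache(maxsize=1)
def _delta_table() -> np.ndarray:
    """For each residual r in [0, 99]: channel deltas (da, db, dc) with
    30*da + 59*db + 11*dc = r, minimizing the largest channel move."""
    best = {}
    rng = range(-9, 10)
    for da in rng:
        for db in rng:
            for dc in rng:
                r = 30 * da + 59 * db + 11 * dc
                if 0 <= r <= 99:
                    cost = max(abs(da), abs(db), abs(dc))
                    if r not in best or cost < best[r][0]:
                        best[r] = (cost, (da, db, dc))
    if len(best) != 100:
        raise AssertionError("delta table incomplete")  # pragma: no cover
    return np.array([best[r][1] for r in range(100)], dtype=np.int64)


def encode_gray_exact(target: np.ndarray, purple_strength: float = 1.0) -> np.ndarray:
    """Encode a float gray image as uint8 RGB whose weighted intensity equals
    the target to within 0.005 units, with a purple tint on dark pixels.

    Pixels within ~9 units of pure black/white may be unreachable exactly
    after clipping; those fall back to the nearest achievable value (error
    still well below one intensity unit).
    """
    t = np.clip(np.asarray(target, dtype=np.float64), 0.0, 255.0)
    total = np.rint(100.0 * t).astype(np.int64)  # desired 30R+59G+11B
    g0 = total // 100
    rem = (total - 100 * g0).astype(np.intp)

    deltas = _delta_table()[rem]  # (..., 3)
    chans = g0[..., None] + deltas  # R, G, B

    # purple tint via zero-weight moves, scaled by darkness
    k_target = np.rint(purple_strength * (255.0 - t) / 8.0).astype(np.int64)
    move = np.array([1, -2, 8], dtype=np.int64)
    # largest k keeping all channels in range
    with np.errstate(divide="ignore", invalid="ignore"):
        k_max = np.minimum.reduce(
            [
                (255 - chans[..., 0]) // 1,
                chans[..., 1] // 2,
                (255 - chans[..., 2]) // 8,
            ]
        )
    k = np.clip(k_target, 0, np.maximum(k_max, 0))
    chans = chans + k[..., None] * move

    bad = np.any((chans < 0) | (chans > 255), axis=-1)
    if bad.any():
        flat = chans.reshape(-1, 3)
        tot_flat = total.reshape(-1)
        for i in np.flatnonzero(bad.reshape(-1)):
            flat[i] = _nearest_valid(int(tot_flat[i]))
        chans = flat.reshape(chans.shape)
    return chans.astype(np.uint8)


def _nearest_valid(total: int) -> tuple[int, int, int]:
    """Brute fallback near black/white: closest achievable 30R+59G+11B."""
    g = int(np.clip(total // 100, 0, 255))
    best = None
    for R in range(max(0, g - 10), min(256, g + 11)):
        for G in range(max(0, g - 10), min(256, g + 11)):
            # solve B directly
            b = round((total - 30 * R - 59 * G) / 11)
            for B in (b - 1, b, b + 1):
                if 0 <= B <= 255:
                    err = abs(30 * R + 59 * G + 11 * B - total)
                    if best is None or err < best[0]:
                        best = (err, (R, G, B))
    return best[1]


# ---------------------------------------------------------------------------
# Calibration batches (tables only)

def make_calibration_batch(
    n_papers: int,
    standards: Sequence[float] = DEFAULT_STANDARDS,
    replicates: int = 3,
    noise_sd: float = 0.0,
    outliers: Sequence[OutlierSpec] = (),
    seed: int = 0,
    slope: float = DEFAULT_SLOPE,
    intercept: float = DEFAULT_INTERCEPT,
) -> tuple[pd.DataFrame, FixtureTruth]:
    """Simulated calibration-spot table for ``n_papers`` papers.

    Spot intensity = slope*c + intercept + N(0, noise_sd), clipped to
    [0, 255]. Designated outlier papers get an additive shift at one
    concentration for ``n_spots`` of their replicates. Deterministic per
    seed; the schema matches spot_analysis.spots_to_table.
    """
    if n_papers < 1 or replicates < 1:
        raise DataError("n_papers and replicates must be >= 1")
    paper_ids = [f"paper{p:02d}" for p in range(n_papers)]
    for o in outliers:
        if o.paper_id not in paper_ids:
            raise DataError(f"outlier spec references unknown paper {o.paper_id!r}")
        if o.concentration not in set(standards):
            raise DataError(
                f"outlier spec concentration {o.concentration} not a standard"
            )

    rng = np.random.default_rng(seed)
    rows = []
    truth_conc: dict[str, float] = {}
    truth_int: dict[str, float] = {}
    for pid in paper_ids:
        cell = 0
        for si, conc in enumerate(standards):
            shift_left = 0
            for o in outliers:
                if o.paper_id == pid and o.concentration == conc:
                    shift_left = o.n_spots
                    shift_amt = o.shift
            for rep in range(replicates):
                target = slope * conc + intercept
                if shift_left > 0:
                    target += shift_amt
                    shift_left -= 1
                value = float(np.clip(target + rng.normal(0.0, noise_sd) if noise_sd else target, 0.0, 255.0))
                key = f"{pid}:{cell}"
                truth_conc[key] = conc
                truth_int[key] = target
                rows.append(
                    {
                        "paper_id": pid,
                        "grid_cell": cell,
                        "concentration_mM": conc,
                        "mean_intensity": value,
                        "area_px": 0,
                        "centroid_row": float(si),
                        "centroid_col": float(rep),
                        "touches_border": False,
                    }
                )
                cell += 1
    truth = FixtureTruth(
        slope=slope,
        intercept=intercept,
        standards=tuple(standards),
        noise_sd=noise_sd,
        seed=seed,
        spot_concentrations=truth_conc,
        spot_intensities=truth_int,
        outliers=tuple(outliers),
    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Blot and root-scan images

def _polyline_distance(
    shape: tuple[int, int], points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel distance to a polyline and arc-length of the closest point."""
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    px = np.stack([rr, cc], axis=-1).astype(np.float64)
    dist = np.full((h, w), np.inf)
    arc = np.zeros((h, w))
    s0 = 0.0
    for a, b in zip(points[:-1], points[1:]):
        ab = b - a
        seg_len = float(np.hypot(*ab))
        if seg_len == 0:
            continue
        t = ((px - a) @ ab) / (seg_len**2)
        t = np.clip(t, 0.0, 1.0)
        proj = a + t[..., None] * ab
        d = np.hypot(px[..., 0] - proj[..., 0], px[..., 1] - proj[..., 1])
        closer = d < dist
        dist[closer] = d[closer]
        arc[closer] = s0 + t[closer] * seg_len
        s0 += seg_len
    return dist, arc


def make_blot_image(
    width: int = 200,
    height: int = 200,
    grid: GridSpec | None = None,
    standards: Sequence[float] = DEFAULT_STANDARDS,
    slope: float = DEFAULT_SLOPE,
    intercept: float = DEFAULT_INTERCEPT,
    background_intensity: float | None = None,
    trace_points: Sequence[tuple[float, float]] = (),
    trace_profile: Sequence[float] = (),
    trace_sigma: float = 3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    purple_strength: float = 1.0,
) -> tuple[RGBImage, FixtureTruth]:
    """Synthesize a scanned blot paper: bright background near the intercept,
    dark calibration disks whose gray level follows the generating line, and
    an optional root-shaped band with Gaussian cross-section whose centerline
    follows the per-arc-length concentration profile.

    Disk intensities are exact (see encode_gray_exact); grid row i carries
    standards[i] replicated across the columns.
    """
    grid = grid or GridSpec(rows=3, cols=3, pitch=40.0, origin=(30.0, 30.0), expected_radius=10.0)
    if grid.rows != len(standards):
        raise DataError("grid must have one row per standard")
    bg = intercept if background_intensity is None else background_intensity
    centers = grid.expected_centers()
    for r, c in centers:
        if not (grid.expected_radius <= r < height - grid.expected_radius
                and grid.expected_radius <= c < width - grid.expected_radius):
            raise LayoutError("grid does not fit inside the image")

    target = np.full((height, width), float(bg))
    rr, cc = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
    truth_conc: dict[str, float] = {}
    truth_int: dict[str, float] = {}
    for k, (cy, cx) in enumerate(centers):
        conc = standards[k // grid.cols]
        level = slope * conc + intercept
        disk = (rr - cy) ** 2 + (cc - cx) ** 2 <= grid.expected_radius**2
        target[disk] = level
        truth_conc[str(k)] = conc
        truth_int[str(k)] = level

    pts = np.asarray(trace_points, dtype=float)
    if pts.size:
        if len(trace_profile) != len(pts):
            raise DataError("trace_profile must give one concentration per point")
        # reject traces whose band runs into the grid disks
        clearance = grid.expected_radius + 3 * trace_sigma
        for cy, cx in centers:
            center = np.array([cy, cx])
            for a, b in zip(pts[:-1], pts[1:]):
                ab = b - a
                denom = float(ab @ ab)
                t = 0.0 if denom == 0 else float(np.clip((center - a) @ ab / denom, 0, 1))
                if np.hypot(*(a + t * ab - center)) < clearance:
                    raise LayoutError("root trace overlaps the calibration grid")
        dist, arc = _polyline_distance((height, width), pts)
        seg = np.hypot(*np.diff(pts, axis=0).T)
        arc_knots = np.concatenate([[0.0], np.cumsum(seg)])
        prof = np.interp(arc, arc_knots, np.asarray(trace_profile, dtype=float))
        center_level = slope * prof + intercept
        band = np.exp(-(dist**2) / (2.0 * trace_sigma**2))
        mask = dist <= 4.0 * trace_sigma
        target[mask] = target[mask] - (target[mask] - center_level[mask]) * band[mask]
        # pin the discrete centerline pixels to the exact profile level
        center_px = dist <= 0.5
        target[center_px] = center_level[center_px]

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        target = target + rng.normal(0.0, noise_sd, size=target.shape)
    target = np.clip(target, 0.0, 255.0)

    image = RGBImage(encode_gray_exact(target, purple_strength=purple_strength))
    truth = FixtureTruth(
        slope=slope,
        intercept=intercept,
        standards=tuple(standards),
        noise_sd=noise_sd,
        seed=seed,
        spot_concentrations=truth_conc,
        spot_intensities=truth_int,
        disk_centers=tuple((float(r), float(c)) for r, c in centers),
        disk_radius=grid.expected_radius,
        trace_points=tuple(map(tuple, pts.tolist())) if pts.size else (),
        trace_profile=tuple(float(v) for v in trace_profile),
    )
    return image, truth


def make_root_scan(
    trace_points: Sequence[tuple[float, float]],
    width: int = 200,
    height: int = 200,
    band_sigma: float = 2.5,
    seed: int = 0,
) -> RGBImage:
    """Blue-background scan with a pale root band along the trace."""
    pts = np.asarray(trace_points, dtype=float)
    if pts.shape[0] < 2:
        raise DataError("trace needs at least 2 points")
    dist, _ = _polyline_distance((height, width), pts)
    band = np.exp(-(dist**2) / (2.0 * band_sigma**2))
    rng = np.random.default_rng(seed)
    base = np.zeros((height, width, 3))
    base[..., 0] = 40
    base[..., 1] = 60
    base[..., 2] = 150  # blue germination-paper background
    pale = np.array([225.0, 220.0, 200.0])
    out = base + band[..., None] * (pale - base)
    out += rng.normal(0.0, 1.0, size=out.shape)
    return RGBImage(np.clip(np.rint(out), 0, 255))
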