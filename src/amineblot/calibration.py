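"""Calibration of blot papers: fence-based outlier rejection, linear
calibration with confidence intervals, inverse prediction, and resolution
estimation.

The calibration model is ordinary least squares of spot mean intensity (y)
on standard free-amine concentration (x, mM):

    intensity = slope * concentration + intercept

Outlier papers are removed before fitting: for each standard concentration,
spot intensities are pooled across all papers in the batch, quartiles and
the interquartile range are computed, and a spot is flagged when it falls
outside [Q1 - k*IQR, Q3 + k*IQR] (default k = 0.5). A paper is removed when
at least ``min_outlier_spots`` (default 2) of its spots are flagged at a
single concentration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DataError, DegenerateModelError


@dataclass(frozen=True)
class CalibrationSpot:
    """One measured calibration spot: paper, standard concentration, intensity."""

    paper_id: str
    concentration: float
    mean_intensity: float

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise DataError("standard concentration must be > 0")
        if not 0.0 <= self.mean_intensity <= 255.0:
            raise DataError("mean_intensity must lie in [0, 255]")


@dataclass(frozen=True)
class FenceParams:
    """Tukey-fence parameters for outlier spots and papers."""

    k: float = 0.5
    min_outlier_spots: int = 2

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise DataError("fence multiplier k must be > 0")
        if self.min_outlier_spots < 1:
            raise DataError("min_outlier_spots must be >= 1")


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted calibration line with the diagnostics needed for intervals.

    ``residual_se`` is sqrt(SSE / (n-2)); ``sxx`` is sum((x - x_mean)^2).
    ``clamp_max`` bounds inverse predictions (default: the top standard).
    """

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    residual_se: float
    x_mean: float
    sxx: float
    level: float = 0.95
    clamp_max: float | None = None
    retained_papers: tuple[str, ...] = field(default=())
    removed_papers: tuple[str, ...] = field(default=())

    def predict(self, x):
        """Mean intensity predicted at concentration ``x``."""
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def slope_ci(self) -> tuple[float, float]:
        """Confidence interval for the slope at the model's level."""
        se = self.residual_se / np.sqrt(self.sxx)
        t = sps.t.ppf(0.5 + self.level / 2, self.n - 2)
        return (self.slope - t * se, self.slope + t * se)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n": self.n,
            "residual_se": self.residual_se,
            "x_mean": self.x_mean,
            "sxx": self.sxx,
            "level": self.level,
            "clamp_max": self.clamp_max,
            "retained_papers": list(self.retained_papers),
            "removed_papers": list(self.removed_papers),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        d = dict(d)
        d["retained_papers"] = tuple(d.get("retained_papers", ()))
        d["removed_papers"] = tuple(d.get("removed_papers", ()))
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    """Q1, Q3 and IQR by linear interpolation of order statistics.

    Uses the h = (n-1)p definition (numpy/spreadsheet default): e.g.
    [1, 2, 3, 4] gives Q1 = 1.75, Q3 = 3.25, IQR = 1.5.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise DataError("quartiles require at least 2 values")
    q1, q3 = np.percentile(arr, [25, 75], method="linear")
    return float(q1), float(q3), float(q3 - q1)


def fence_outliers(
    values: Sequence[float], fence: FenceParams = FenceParams()
) -> np.ndarray:
    """Boolean flags: True where a value lies outside the Tukey fences
    [Q1 - k*IQR, Q3 + k*IQR]."""
    arr = np.asarray(values, dtype=float)
    q1, q3, iqr = quartiles(arr)
    return (arr < q1 - fence.k * iqr) | (arr > q3 + fence.k * iqr)


@dataclass(frozen=True)
class OutlierReport:
    """Partition of a batch into retained and removed papers."""

    retained: tuple[str, ...]
    removed: tuple[str, ...]
    spot_flags: tuple[bool, ...]  # aligned with the input spot order
    reasons: dict  # removed paper id -> {concentration: n_flagged}


def flag_outlier_papers(
    spots: Sequence[CalibrationSpot], fence: FenceParams = FenceParams()
) -> OutlierReport:
    """Flag outlier papers using per-concentration pooled fences.

    Fences are computed per standard concentration, pooling that
    concentration's spots across every paper in the batch. A paper is
    removed iff at a single concentration at least ``fence.min_outlier_spots``
    of its spots are flagged. Every paper must contribute spots at every
    concentration present in the batch.
    """
    if not spots:
        raise DataError("no calibration spots supplied")
    papers = sorted({s.paper_id for s in spots})
    concs = sorted({s.concentration for s in spots})
    by_paper_conc: dict[tuple[str, float], list[int]] = {}
    for i, s in enumerate(spots):
        by_paper_conc.setdefault((s.paper_id, s.concentration), []).append(i)
    for p in papers:
        for c in concs:
            if (p, c) not in by_paper_conc:
                raise DataError(
                    f"paper {p!r} has no spots at concentration {c} mM"
                )

    flags = np.zeros(len(spots), dtype=bool)
    for c in concs:
        idx = [i for i, s in enumerate(spots) if s.concentration == c]
        flags[idx] = fence_outliers([spots[i].mean_intensity for i in idx], fence)

    removed: list[str] = []
    reasons: dict[str, dict[float, int]] = {}
    for p in papers:
        counts = {
            c: int(flags[by_paper_conc[(p, c)]].sum()) for c in concs
        }
        bad = {c: k for c, k in counts.items() if k >= fence.min_outlier_spots}
        if bad:
            removed.append(p)
            reasons[p] = bad
    retained = [p for p in papers if p not in removed]
    return OutlierReport(
        retained=tuple(retained),
        removed=tuple(removed),
        spot_flags=tuple(bool(f) for f in flags),
        reasons=reasons,
    )


def fit_calibration(
    spots: Sequence[CalibrationSpot],
    level: float = 0.95,
    clamp_max: float | None = None,
) -> CalibrationModel:
    """Ordinary least squares of mean intensity on concentration.

    Closed-form normal equations; the two-sided p-value tests zero slope.
    ``clamp_max`` defaults to the highest standard concentration.
    """
    if len(spots) < 3:
        raise DataError("calibration requires at least 3 spots")
    x = np.asarray([s.concentration for s in spots], dtype=float)
    y = np.asarray([s.mean_intensity for s in spots], dtype=float)
    if np.unique(x).size < 2:
        raise DegenerateModelError("all concentrations identical: cannot fit a line")

    n = x.size
    x_mean = float(x.mean())
    y_mean = float(y.mean())
    sxx = float(np.sum((x - x_mean) ** 2))
    sxy = float(np.sum((x - x_mean) * (y - y_mean)))
    slope = sxy / sxx
    intercept = y_mean - slope * x_mean

    resid = y - (slope * x + intercept)
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y - y_mean) ** 2))
    r_squared = 1.0 if sst == 0.0 else 1.0 - sse / sst
    residual_se = float(np.sqrt(max(sse, 0.0) / (n - 2)))

    se_slope = residual_se / np.sqrt(sxx)
    if se_slope == 0.0:
        p_value = 0.0
    else:
        tstat = slope / se_slope
        p_value = float(2 * sps.t.sf(abs(tstat), n - 2))

    return CalibrationModel(
        slope=slope,
        intercept=intercept,
        r_squared=float(np.clip(r_squared, 0.0, 1.0)),
        p_value=p_value,
        n=n,
        residual_se=residual_se,
        x_mean=x_mean,
        sxx=sxx,
        level=level,
        clamp_max=float(np.max(x)) if clamp_max is None else float(clamp_max),
        retained_papers=tuple(sorted({s.paper_id for s in spots})),
    )


def calibrate_batch(
    spots: Sequence[CalibrationSpot],
    fence: FenceParams = FenceParams(),
    level: float = 0.95,
    clamp_max: float | None = None,
) -> tuple[CalibrationModel, OutlierReport]:
    """Full calibration workflow: remove outlier papers, then fit on the rest."""
    report = flag_outlier_papers(spots, fence)
    kept = [s for s in spots if s.paper_id in report.retained]
    if not kept:
        raise DataError("every paper was removed as an outlier; nothing to fit")
    model = fit_calibration(kept, level=level, clamp_max=clamp_max)
    model = replace(model, removed_papers=report.removed)
    return model, report


def ci_mean_response(
    model: CalibrationModel, x: float, prediction: bool = False
) -> tuple[float, float]:
    """Confidence interval for the mean response (the regression line) at x.

    With ``prediction=True`` returns a prediction interval for a new
    observation instead (an extra +1 inside the square root).
    """
    if model.n <= 2:
        raise DegenerateModelError("interval requires n > 2")
    t = sps.t.ppf(0.5 + model.level / 2, model.n - 2)
    lev = 1.0 / model.n + (x - model.x_mean) ** 2 / model.sxx
    if prediction:
        lev += 1.0
    half = t * model.residual_se * np.sqrt(lev)
    yhat = float(model.predict(x))
    return (yhat - half, yhat + half)


def intensity_to_conc(model: CalibrationModel, intensity):
    """Inverse prediction: concentration estimated from intensity.

    x_hat = (intensity - intercept) / slope, clamped to [0, clamp_max].
    Accepts scalars or arrays.
    """
    if model.slope == 0:
        raise DegenerateModelError("zero slope: cannot invert the calibration line")
    arr = np.asarray(intensity, dtype=float)
    xhat = (arr - model.intercept) / model.slope
    hi = np.inf if model.clamp_max is None else model.clamp_max
    out = np.clip(xhat, 0.0, hi)
    return float(out) if np.isscalar(intensity) else out


def estimate_resolution(
    model: CalibrationModel, standards: Iterable[float]
) -> tuple[list[float], float]:
    """Concentration resolution implied by the CI width at each standard.

    For each standard x the CI intensity range (upper - lower) is divided by
    |slope| to yield a concentration range; the mean across standards is
    returned alongside the per-standard list.
    """
    xs = list(standards)
    if not xs:
        raise DataError("standards must be non-empty")
    ranges = []
    for x in xs:
        lo, hi = ci_mean_response(model, x)
        ranges.append((hi - lo) / abs(model.slope))
    return ranges, float(np.mean(ranges))


def spots_from_table(df) -> list[CalibrationSpot]:
    """Build CalibrationSpots from a spot table (needs paper_id,
    concentration_mM, mean_intensity columns); rows without a standard
    concentration are skipped."""
    required = {"paper_id", "concentration_mM", "mean_intensity"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"spot table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        c = row["concentration_mM"]
        if c is None or (isinstance(c, float) and np.isnan(c)):
            continue
        out.append(
            CalibrationSpot(
                paper_id=str(row["paper_id"]),
                concentration=float(c),
                mean_intensity=float(row["mean_intensity"]),
            )
        )
    return out
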