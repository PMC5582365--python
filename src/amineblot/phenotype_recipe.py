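"""Root-length / growth-rate arithmetic and mock-exudate free-amine accounting."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass(frozen=True)
class RootTrace:
    """A manually traced root polyline in pixel coordinates, with a scale."""

    points: tuple  # ordered ((row, col), ...) pixel coordinates
    scale: float  # cm per pixel

    def __post_init__(self) -> None:
        pts = tuple((float(r), float(c)) for r, c in self.points)
        if len(pts) < 2:
            raise DataError("a root trace needs at least 2 points")
        if self.scale <= 0:
            raise DataError("scale must be > 0")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class LengthSeries:
    """Day-indexed primary-root lengths (cm), days strictly increasing."""

    entries: dict  # {day: length_cm}

    def __post_init__(self) -> None:
        e = {int(d): float(v) for d, v in self.entries.items()}
        days = sorted(e)
        if any(e[d] < 0 for d in days):
            raise DataError("lengths must be >= 0")
        object.__setattr__(self, "entries", {d: e[d] for d in days})


@dataclass(frozen=True)
class MockExudateRecipe:
    """Named components with concentrations (mM) and free-amine group counts."""

    components: tuple  # ((name, concentration_mM, free_amine_groups), ...)

    def __post_init__(self) -> None:
        comps = tuple(
            (str(n), float(c), int(g)) for n, c, g in self.components
        )
        for name, conc, groups in comps:
            if conc <= 0:
                raise DataError(f"{name}: concentration must be > 0")
            if groups < 0:
                raise DataError(f"{name}: free_amine_groups must be >= 0")
        object.__setattr__(self, "components", comps)


#: The 70X mock exudate: amino acids carry one free amine group each,
#: sugars and organic acids none. Totals 23.9 mM free amine.
MOCK_EXUDATE_70X = MockExudateRecipe(
    components=(
        ("glucose", 18.4, 0),
        ("fructose", 18.4, 0),
        ("sucrose", 9.2, 0),
        ("citric acid", 9.2, 0),
        ("lactic acid", 18.4, 0),
        ("succinic acid", 13.8, 0),
        ("alanine", 9.2, 1),
        ("serine", 9.2, 1),
        ("glutamic acid", 5.5, 1),
    )
)


def polyline_length(trace: RootTrace) -> float:
    """Total Euclidean length of the trace polyline, in cm."""
    pts = np.asarray(trace.points, dtype=float)
    seg = np.diff(pts, axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum() * trace.scale)


def growth_rate(series: LengthSeries) -> dict[int, float]:
    """Two-day growth rates: R_D = (L_{D+2} - L_D) / 2, cm/day.

    Days lacking a D+2 partner are omitted; a sparse series yields sparse
    rates.
    """
    e = series.entries
    return {d: (e[d + 2] - e[d]) / 2.0 for d in e if d + 2 in e}


def total_free_amine(recipe: MockExudateRecipe) -> float:
    """Total free-amine concentration: sum of conc x amine-group count (mM)."""
    return sum(c * g for _, c, g in recipe.components)


def dilute(recipe: MockExudateRecipe, factor: float) -> MockExudateRecipe:
    """Divide every component concentration by ``factor`` (> 0)."""
    if factor <= 0:
        raise DataError("dilution factor must be > 0")
    return MockExudateRecipe(
        components=tuple((n, c / factor, g) for n, c, g in recipe.components)
    )


# ---------------------------------------------------------------------------
# CSV / JSON interfaces

def read_trace_csv(path: str | Path, scale: float) -> dict[int, RootTrace]:
    """Read traces from CSV columns (day, point_index, row, col) -> {day: trace}."""
    df = pd.read_csv(path)
    required = {"day", "point_index", "row", "col"}
    if missing := required - set(df.columns):
        raise DataError(f"trace CSV missing columns: {sorted(missing)}")
    out = {}
    for day, grp in df.groupby("day"):
        grp = grp.sort_values("point_index")
        out[int(day)] = RootTrace(
            points=tuple(zip(grp["row"], grp["col"])), scale=scale
        )
    return out


def read_length_csv(path: str | Path) -> dict[str, LengthSeries]:
    """Read length series from CSV (seedling_id, day, length_cm)."""
    df = pd.read_csv(path)
    required = {"seedling_id", "day", "length_cm"}
    if missing := required - set(df.columns):
        raise DataError(f"length CSV missing columns: {sorted(missing)}")
    return {
        str(sid): LengthSeries(entries=dict(zip(grp["day"], grp["length_cm"])))
        for sid, grp in df.groupby("seedling_id")
    }


def recipe_to_json(recipe: MockExudateRecipe, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            [
                {"name": n, "concentration_mM": c, "free_amine_groups": g}
                for n, c, g in recipe.components
            ],
            indent=2,
        )
    )


def recipe_from_json(path: str | Path) -> MockExudateRecipe:
    data = json.loads(Path(path).read_text())
    return MockExudateRecipe(
        components=tuple(
            (d["name"], d["concentration_mM"], d["free_amine_groups"]) for d in data
        )
    )
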