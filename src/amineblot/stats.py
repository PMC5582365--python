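"""Two-factor ANOVA with Tukey HSD pairwise comparisons, and
limit-of-detection determination against a zero-concentration control.

The model is fixed-effects with the primary factor (concentration or day)
plus paper, no interaction by default. Tukey HSD p-values come from the
studentized-range distribution using the two-way model's residual mean
square (Tukey-Kramer for unequal cell sizes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import studentized_range

from .errors import DataError


@dataclass(frozen=True)
class IntensityObservation:
    """One spot intensity with its primary-factor level and source paper."""

    value: float
    level: float  # concentration in mM (0 = water control) or day index
    paper_id: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 255.0:
            raise DataError("intensity value must lie in [0, 255]")


@dataclass(frozen=True)
class Anova2Result:
    """ANOVA table, residual diagnostics, and the Tukey pairwise table."""

    anova_table: pd.DataFrame
    pairwise: pd.DataFrame  # level_a, level_b, estimate, p_value, significant
    mse: float
    df_resid: float
    alpha: float


def _to_frame(observations: Sequence[IntensityObservation]) -> pd.DataFrame:
    if not observations:
        raise DataError("no observations supplied")
    return pd.DataFrame(
        {
            "value": [o.value for o in observations],
            "level": [o.level for o in observations],
            "paper": [o.paper_id for o in observations],
        }
    )


def anova2_tukey(
    observations: Sequence[IntensityObservation],
    alpha: float = 0.01,
    interaction: bool = False,
) -> Anova2Result:
    """Two-factor fixed-effects ANOVA plus Tukey HSD over primary-factor pairs.

    Requires >= 2 levels of the primary factor and a non-empty cell for every
    (level, paper) combination; an empty cell raises a DataError naming it.
    """
    df = _to_frame(observations)
    levels = sorted(df["level"].unique())
    papers = sorted(df["paper"].unique())
    if len(levels) < 2:
        raise DataError("need at least 2 levels of the primary factor")
    sizes = df.groupby(["level", "paper"]).size()
    for lv in levels:
        for p in papers:
            if (lv, p) not in sizes.index:
                raise DataError(f"empty cell: level={lv}, paper={p!r}")

    if len(papers) == 1:
        formula = "value ~ C(level)"  # paper factor degenerates to the intercept
    elif interaction:
        formula = "value ~ C(level) * C(paper)"
    else:
        formula = "value ~ C(level) + C(paper)"
    fit = smf.ols(formula, data=df).fit()
    # constant response -> zero-variance model; anova_lm emits nan rows but
    # the pairwise table below is still well defined (no pair significant)
    with np.errstate(divide="ignore", invalid="ignore"):
        table = sm.stats.anova_lm(fit, typ=2)
    mse = float(fit.mse_resid)
    df_resid = float(fit.df_resid)

    k = len(levels)
    means = df.groupby("level")["value"].mean()
    ns = df.groupby("level")["value"].size()
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            diff = float(means[b] - means[a])
            se = np.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b]) / 2.0)
            if se == 0.0:
                p = 0.0 if diff != 0.0 else 1.0
            else:
                q = abs(diff) / se
                p = float(studentized_range.sf(q, k, df_resid))
            rows.append(
                {
                    "level_a": a,
                    "level_b": b,
                    "estimate": diff,
                    "p_value": p,
                    "significant": bool(p < alpha),
                }
            )
    pairwise = pd.DataFrame(rows)
    return Anova2Result(
        anova_table=table, pairwise=pairwise, mse=mse, df_resid=df_resid, alpha=alpha
    )


def detection_limit(
    observations: Sequence[IntensityObservation],
    alpha: float = 0.01,
    control_level: float = 0.0,
) -> float | None:
    """Smallest concentration distinguishable from the control.

    Returns the smallest concentration whose Tukey comparison against the
    control has p < alpha, provided every larger concentration is also
    significant; None when no concentration qualifies. This matches the
    convention that everything above the reported limit must also differ
    from the control.
    """
    df = _to_frame(observations)
    if control_level not in set(df["level"]):
        raise DataError(f"control level {control_level} missing from observations")
    result = anova2_tukey(observations, alpha=alpha)
    pw = result.pairwise
    vs_control = {}
    for _, row in pw.iterrows():
        if row["level_a"] == control_level:
            vs_control[row["level_b"]] = bool(row["significant"])
        elif row["level_b"] == control_level:
            vs_control[row["level_a"]] = bool(row["significant"])

    concs = sorted(vs_control, reverse=True)  # scan downward from the top
    limit = None
    for c in concs:
        if vs_control[c]:
            limit = c
        else:
            break  # a non-significant level interrupts the run from the top
    return limit
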