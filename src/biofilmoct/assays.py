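"""Plate-assay formulas and the two-sample significance test.

Covers the sedimentation (autoaggregation) percentage, the WST-8 viability
percentage, ratio-to-control fold change, and Welch's unequal-variance
t-test.  The t statistic, Welch–Satterthwaite degrees of freedom and the
two-sided p-value are computed from their defining formulas; the p-value
uses the regularised incomplete beta function for the t CDF.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import betainc


@dataclass
class SedimentationSeries:
    """Paired OD600 readings of a static sedimentation (autoaggregation) assay.

    ``od_final`` is read at the top of the undisturbed tube, ``od_initial``
    from a parallel tube vortexed just before reading, at the same time
    points (hours).  ``turbidity_percent`` is 100 × od_final / od_initial.
    """

    time_points_h: list[float]
    od_final: list[float]
    od_initial: list[float]
    turbidity_percent: list[float] | None = None

    def __post_init__(self) -> None:
        n = len(self.time_points_h)
        if not (len(self.od_final) == len(self.od_initial) == n):
            raise ValueError("time, od_final and od_initial series must have equal length")
        if any(v < 0 for v in self.od_final) or any(v < 0 for v in self.od_initial):
            raise ValueError("OD readings must be >= 0")
        if self.turbidity_percent is None:
            self.turbidity_percent = [
                autoaggregation_percent(f, i) for f, i in zip(self.od_final, self.od_initial)
            ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_h": self.time_points_h,
            "od_final": self.od_final,
            "od_initial": self.od_initial,
            "turbidity_percent": self.turbidity_percent,
        })


@dataclass
class ViabilityReading:
    """Absorbance triple (450 nm) of one WST-8 viability well."""

    a_test: float
    a_control: float
    a_background: float

    def __post_init__(self) -> None:
        if self.a_control == self.a_background:
            raise ValueError("a_control must differ from a_background (zero denominator)")


def autoaggregation_percent(od_final: float, od_initial: float) -> float:
    """Turbidity at the tube top as a percentage of the vortexed control.

    100 × OD_final / OD_initial.  Values above 100 (more turbid than the
    vortexed tube) are physically odd but reported as-is with a warning.
    """
    if od_initial <= 0:
        raise ValueError(f"od_initial must be > 0, got {od_initial}")
    if od_final < 0:
        raise ValueError(f"od_final must be >= 0, got {od_final}")
    pct = od_final / od_initial * 100.0
    if pct > 100.0:
        warnings.warn(f"autoaggregation percentage {pct:.1f} exceeds 100", stacklevel=2)
    return pct


def viability_percent(r: ViabilityReading) -> float:
    """Background-corrected viability: (A_test − A_bg) / (A_ctrl − A_bg) × 100.

    May exceed 100 or go negative when the test well out- or under-performs
    the control; both are reported as-is with a warning.
    """
    pct = (r.a_test - r.a_background) / (r.a_control - r.a_background) * 100.0
    if pct > 100.0 or pct < 0.0:
        warnings.warn(f"viability {pct:.1f}% outside [0, 100]", stacklevel=2)
    return pct


def fold_change(treated: float, control: float) -> float:
    """Ratio of a treated measurement to its (positive) negative control."""
    if control <= 0:
        raise ValueError(f"control must be > 0, got {control}")
    return treated / control


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float
    degenerate: bool = False


def _t_sf_two_sided(t: float, df: float) -> float:
    """Two-sided p of a t statistic via the regularised incomplete beta."""
    if math.isinf(t):
        return 0.0
    return float(betainc(df / 2.0, 0.5, df / (df + t * t)))


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance two-sample t-test, two-sided.

    t = (x̄ − ȳ) / sqrt(s²x/nx + s²y/ny) with Welch–Satterthwaite degrees
    of freedom.  When both samples have zero variance the statistic is
    undefined: equal means give (t=0, p=1) and unequal means (t=±inf, p=0),
    both flagged ``degenerate``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError(f"each sample needs n >= 2, got n_x={nx}, n_y={ny}")

    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny

    if se2 == 0.0:
        warnings.warn("both samples have zero variance; t-test degenerate", stacklevel=2)
        if mx == my:
            return WelchResult(t=0.0, df=float(nx + ny - 2), p=1.0, degenerate=True)
        return WelchResult(t=math.copysign(math.inf, mx - my),
                           df=float(nx + ny - 2), p=0.0, degenerate=True)

    t = (mx - my) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return WelchResult(t=float(t), df=float(df), p=_t_sf_two_sided(t, df))


def read_sedimentation_csv(path) -> SedimentationSeries:
    """Load a sedimentation assay CSV with columns time_h, od_final, od_initial."""
    df = pd.read_csv(path)
    missing = {"time_h", "od_final", "od_initial"} - set(df.columns)
    if missing:
        raise ValueError(f"sedimentation CSV missing columns: {sorted(missing)}")
    return SedimentationSeries(
        time_points_h=df["time_h"].tolist(),
        od_final=df["od_final"].tolist(),
        od_initial=df["od_initial"].tolist(),
    )


def read_viability_csv(path) -> list[ViabilityReading]:
    """Load a viability CSV with columns a_test, a_control, a_background."""
    df = pd.read_csv(path)
    missing = {"a_test", "a_control", "a_background"} - set(df.columns)
    if missing:
        raise ValueError(f"viability CSV missing columns: {sorted(missing)}")
    return [ViabilityReading(r.a_test, r.a_control, r.a_background)
            for r in df.itertuples(index=False)]
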