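"""Spoilage-indicator kinetics and rejection-threshold crossings.

Ice-stored fish lose quality through two broadly sequential mechanisms —
autolytic enzymatic degradation, then microbial action — which leaves
distinct fingerprints on each instrumental indicator:

* **Torrymeter** (muscle dielectric) readings fall in two linear phases
  with a breakpoint at the handover between the mechanisms; fitted by a
  discrete exhaustive breakpoint search with an independent least-squares
  line per phase.
* **Microbial counts** (total viable counts, H2S producers) grow
  log-linearly; fitted on the log10 cfu/cm2 scale.
* **TMA** (trimethylamine) accumulates slowly and then accelerates; the
  default model is monotone piecewise-linear interpolation because no
  single parametric form is defensible at day-resolution sampling.  A
  log-linear (exponential) alternative is available behind a flag.
* **pH** drifts weakly; a t-test on the regression slope decides whether
  the drift is distinguishable from noise.

Each indicator contributes a rejection-day estimate: the first storage day
at which its fitted curve crosses the assay's rejection criterion, with a
whole-day (floor, ceil) bracket to mirror how trial data are tabulated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ASSAYS",
    "AssaySeries",
    "SegmentedFit",
    "GrowthFit",
    "CrossingEstimate",
    "PHTrend",
    "fit_two_phase",
    "crossing_from_two_phase",
    "fit_growth",
    "crossing_from_growth",
    "tma_crossing",
    "tma_crossing_exponential",
    "ph_trend",
    "read_assay_series",
    "write_assay_series",
]

ASSAYS = ("torrymeter", "tvc_nt", "tvc_ir", "h2s", "tma", "ph")

#: Assays whose values fall as the fish spoils.
DECREASING_ASSAYS = frozenset({"torrymeter"})


@dataclass(frozen=True)
class AssaySeries:
    """Time series of one spoilage indicator.

    ``values`` units depend on the assay: Torrymeter instrument units,
    log10 cfu/cm2 for counts, mg/100 g for TMA, pH units.  Counts are
    stored on the log scale at ingest; zero or negative raw counts are
    rejected there (the log is undefined and plate counts of zero were
    never tabulated for these trials).
    """

    assay: str
    times: np.ndarray
    values: np.ndarray
    replicate_sd: np.ndarray | None = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        if times.ndim != 1 or times.shape != values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(times) and not np.all(np.diff(times) > 0):
            raise ValueError(f"{self.assay}: times must be strictly increasing")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(values))):
            raise ValueError(f"{self.assay}: times and values must be finite")
        if self.replicate_sd is not None:
            sd = np.asarray(self.replicate_sd, dtype=float)
            object.__setattr__(self, "replicate_sd", sd)
            if sd.shape != times.shape or np.any(sd < 0):
                raise ValueError(f"{self.assay}: replicate_sd must be non-negative, per time")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class SegmentedFit:
    """Two independent least-squares lines split at a breakpoint."""

    breakpoint_day: float
    slope1: float
    intercept1: float
    slope2: float
    intercept2: float
    r2_1: float
    r2_2: float
    total_sse: float
    t_min: float
    t_max: float

    def value_at(self, day: float) -> float:
        if day <= self.breakpoint_day:
            return self.intercept1 + self.slope1 * day
        return self.intercept2 + self.slope2 * day


@dataclass(frozen=True)
class GrowthFit:
    """Log-linear microbial growth fit (log10 cfu/cm2 per day)."""

    slope: float
    intercept: float
    r2: float
    t_min: float
    t_max: float


@dataclass(frozen=True)
class CrossingEstimate:
    """First day a fitted indicator reaches its rejection threshold."""

    assay: str
    threshold: float
    crossing_day: float  # nan when status != "crossed"
    interval: tuple[int, int] | None
    status: str  # crossed | before_window | beyond_window


@dataclass(frozen=True)
class PHTrend:
    """Slope of pH on day with a two-sided t-test against zero slope."""

    slope: float
    intercept: float
    p_value: float
    significant: bool
    degenerate: bool  # residual variance numerically zero


def _day_interval(day: float) -> tuple[int, int]:
    lo = math.floor(day)
    return (lo, lo + 1)


def _line_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """slope, intercept, r2, sse of a least-squares line."""
    res = stats.linregress(t, y)
    pred = res.intercept + res.slope * t
    sse = float(np.sum((y - pred) ** 2))
    ssy = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ssy == 0 else 1.0 - sse / ssy
    return float(res.slope), float(res.intercept), r2, sse


def fit_two_phase(series: AssaySeries, min_segment: int = 3) -> SegmentedFit:
    """Segmented two-line fit via exhaustive discrete breakpoint search.

    Every split of the observation times leaving at least ``min_segment``
    points per side is scored by the summed SSE of two independent lines;
    the minimum wins, ties going to the earliest breakpoint so results are
    reproducible on a coarse daily grid.  The breakpoint is reported as the
    midpoint between the two boundary observation times.
    """
    t, y = series.times, series.values
    n = len(t)
    if n < 2 * min_segment:
        raise ValueError(
            f"two-phase fit needs >={2 * min_segment} points, got {n}"
        )
    best = None
    for split in range(min_segment, n - min_segment + 1):
        s1, i1, r1, sse1 = _line_fit(t[:split], y[:split])
        s2, i2, r2_, sse2 = _line_fit(t[split:], y[split:])
        total = sse1 + sse2
        if best is None or total < best[0] - 1e-12:
            bp = 0.5 * (t[split - 1] + t[split])
            best = (total, bp, s1, i1, s2, i2, r1, r2_)
    total, bp, s1, i1, s2, i2, r1, r2_ = best
    return SegmentedFit(
        breakpoint_day=float(bp),
        slope1=s1,
        intercept1=i1,
        slope2=s2,
        intercept2=i2,
        r2_1=r1,
        r2_2=r2_,
        total_sse=float(total),
        t_min=float(t[0]),
        t_max=float(t[-1]),
    )


def _solve_line(threshold, slope, intercept, lo, hi) -> float | None:
    """Day in [lo, hi] where slope*d + intercept == threshold, else None."""
    if slope == 0:
        return lo if math.isclose(intercept, threshold) else None
    d = (threshold - intercept) / slope
    if lo - 1e-9 <= d <= hi + 1e-9:
        return float(min(max(d, lo), hi))
    return None


def crossing_from_two_phase(fit: SegmentedFit, threshold: float) -> CrossingEstimate:
    """First day the two-phase line reaches a (decreasing) threshold.

    Readings are assumed to fall over storage (Torrymeter-style): the
    crossing is the first day the piecewise line drops to the threshold.
    """
    start = fit.value_at(fit.t_min)
    if threshold > start:
        return CrossingEstimate("torrymeter", threshold, float("nan"), None, "before_window")
    d = _solve_line(threshold, fit.slope1, fit.intercept1, fit.t_min, fit.breakpoint_day)
    if d is None:
        v_bp1 = fit.intercept1 + fit.slope1 * fit.breakpoint_day
        v_bp2 = fit.intercept2 + fit.slope2 * fit.breakpoint_day
        if min(v_bp1, v_bp2) <= threshold <= max(v_bp1, v_bp2) or math.isclose(
            threshold, v_bp2
        ):
            # threshold met at (or across the jump of) the breakpoint itself
            d = fit.breakpoint_day
        else:
            d = _solve_line(
                threshold, fit.slope2, fit.intercept2, fit.breakpoint_day, fit.t_max
            )
    if d is None:
        return CrossingEstimate("torrymeter", threshold, float("nan"), None, "beyond_window")
    return CrossingEstimate("torrymeter", threshold, float(d), _day_interval(d), "crossed")


def fit_growth(series: AssaySeries, window: tuple[float, float] | None = None) -> GrowthFit:
    """Least-squares line of log10 counts on day, optionally windowed.

    ``window`` restricts the fit to days within [lo, hi]; useful when a
    population (e.g. H2S producers) lags before entering its exponential
    phase.
    """
    t, y = series.times, series.values
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, y = t[mask], y[mask]
    if len(t) < 2:
        raise ValueError("growth fit needs >=2 points in the window")
    if len(t) == 2:
        slope = (y[1] - y[0]) / (t[1] - t[0])
        intercept = y[0] - slope * t[0]
        slope, intercept, r2 = float(slope), float(intercept), 1.0
    else:
        slope, intercept, r2, _ = _line_fit(t, y)
    if slope < 0:
        warnings.warn(
            f"{series.assay}: fitted growth slope {slope:.3g} is negative; "
            "counts are expected to rise during storage",
            stacklevel=2,
        )
    return GrowthFit(slope=slope, intercept=intercept, r2=r2, t_min=float(t[0]), t_max=float(t[-1]))


def crossing_from_growth(
    fit: GrowthFit, threshold_log10: float, assay: str = "tvc_nt"
) -> CrossingEstimate:
    """Day the fitted log-linear growth line reaches an upper count limit."""
    if fit.slope <= 0:
        return CrossingEstimate(assay, threshold_log10, float("nan"), None, "beyond_window")
    d = (threshold_log10 - fit.intercept) / fit.slope
    if d < 0:
        return CrossingEstimate(assay, threshold_log10, float("nan"), None, "before_window")
    return CrossingEstimate(assay, threshold_log10, float(d), _day_interval(d), "crossed")


def tma_crossing(series: AssaySeries, threshold: float) -> CrossingEstimate:
    """First up-crossing of a TMA limit by piecewise-linear interpolation.

    Non-monotone dips between sampling days are tolerated: the first
    interval whose interpolant reaches the threshold wins.
    """
    t, y = series.times, series.values
    if len(t) == 0:
        raise ValueError("empty TMA series")
    if np.any(y < 0):
        raise ValueError("TMA content cannot be negative")
    if y[0] >= threshold:
        # already at/above the limit when the window opens
        return CrossingEstimate("tma", threshold, float("nan"), None, "before_window")
    for i in range(1, len(t)):
        if y[i] >= threshold:
            frac = (threshold - y[i - 1]) / (y[i] - y[i - 1])
            d = float(t[i - 1] + frac * (t[i] - t[i - 1]))
            return CrossingEstimate("tma", threshold, d, _day_interval(d), "crossed")
    return CrossingEstimate("tma", threshold, float("nan"), None, "beyond_window")


def tma_crossing_exponential(series: AssaySeries, threshold: float) -> CrossingEstimate:
    """Alternative TMA crossing from a log-linear (exponential) fit."""
    t, y = series.times, series.values
    if len(t) < 2:
        raise ValueError("exponential TMA fit needs >=2 points")
    if np.any(y <= 0):
        raise ValueError("exponential TMA model needs strictly positive values")
    slope, intercept, _, _ = _line_fit(t, np.log(y))
    if slope <= 0:
        return CrossingEstimate("tma", threshold, float("nan"), None, "beyond_window")
    d = (math.log(threshold) - intercept) / slope
    if d < t[0]:
        return CrossingEstimate("tma", threshold, float("nan"), None, "before_window")
    return CrossingEstimate("tma", threshold, float(d), _day_interval(d), "crossed")


def ph_trend(series: AssaySeries, alpha: float = 0.05) -> PHTrend:
    """Slope of pH on storage day with a t-test for slope = 0."""
    t, y = series.times, series.values
    if len(t) < 3:
        raise ValueError("pH trend needs >=3 points")
    if np.ptp(y) == 0:
        return PHTrend(slope=0.0, intercept=float(y[0]), p_value=1.0,
                       significant=False, degenerate=True)
    res = stats.linregress(t, y)
    pred = res.intercept + res.slope * t
    sse = float(np.sum((y - pred) ** 2))
    degenerate = sse <= 1e-12 * float(np.sum(y**2))
    p = float(res.pvalue)
    if degenerate:
        # exact line: residual variance 0, p is numerically minimal
        p = min(p, np.finfo(float).tiny)
    return PHTrend(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=p,
        significant=bool(p < alpha),
        degenerate=degenerate,
    )


def read_assay_series(path: str | Path) -> dict[str, AssaySeries]:
    """Read a long-format assay table (assay, day, value[, replicate_sd])."""
    df = pd.read_csv(path)
    required = {"assay", "day", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay table is missing columns {sorted(missing)}")
    out: dict[str, AssaySeries] = {}
    for assay, sub in df.groupby("assay"):
        sub = sub.sort_values("day")
        sd = None
        if "replicate_sd" in sub.columns and sub["replicate_sd"].notna().all():
            sd = sub["replicate_sd"].to_numpy(dtype=float)
        out[str(assay)] = AssaySeries(
            assay=str(assay),
            times=sub["day"].to_numpy(dtype=float),
            values=sub["value"].to_numpy(dtype=float),
            replicate_sd=sd,
        )
    return out


def write_assay_series(series: dict[str, AssaySeries], path: str | Path) -> None:
    rows = []
    for s in series.values():
        for i in range(len(s)):
            rows.append(
                {
                    "assay": s.assay,
                    "day": s.times[i],
                    "value": s.values[i],
                    "replicate_sd": None if s.replicate_sd is None else s.replicate_sd[i],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
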