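"""Quality-index calibration against storage time.

Under ice storage the panel-mean quality index rises near-linearly with
days on ice, so an ordinary least-squares line QI = slope * day + intercept
doubles as (i) a freshness calibration and (ii), inverted, a predictor of
how long a fish of unknown history has been stored.  The estimation error
is expressed in *days* (the unit buyers care about): the root-mean-square
of inverse-predicted minus true day over the calibrated days, with a
leave-one-day-out variant as an honesty check.

A single-latent-variable PLS regression of QI on one predictor collapses
to this same least-squares line, which is why no separate PLS fit exists.

The module also covers panel diagnostics: per-assessor slope/r² against the
panel consensus, and attribute-level importance (|Pearson r| of each
attribute's mean score with day) alongside a PCA of the standardized
day-by-attribute matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "LinearCalibration",
    "DayEstimate",
    "PanelPerformance",
    "AttributeImportance",
    "fit_qi_time",
    "predict_storage_day",
    "remaining_shelf_life",
    "assessor_performance",
    "attribute_importance",
    "attribute_mean_scores",
]

#: Panel-mean QI within one demerit point of the scheme ceiling is treated
#: as saturated: the index stops discriminating time once every parameter
#: sits at its maximum.  Saturated days — and every later day, since the
#: underlying index is non-decreasing — are dropped from the linear fit.
SATURATION_MARGIN = 1.0

#: Importance above this is considered relevant for keeping an attribute.
RELEVANCE_CUTOFF = 0.8


@dataclass(frozen=True)
class LinearCalibration:
    """OLS calibration of panel-mean QI on days of ice storage."""

    slope: float
    intercept: float
    r2: float
    residual_sd: float
    n_days: int
    rmse_days: float
    rmse_days_loo: float

    @property
    def df(self) -> int:
        return self.n_days - 2


@dataclass(frozen=True)
class DayEstimate:
    """Inverse-predicted storage day with a t-based interval."""

    day: float
    lower: float
    upper: float
    clipped: bool


@dataclass(frozen=True)
class PanelPerformance:
    """Per-assessor regression diagnostics against the panel consensus.

    ``table`` columns: assessor_id, slope, intercept, r2, n_days, flagged.
    """

    table: pd.DataFrame
    slope_band: tuple[float, float]


@dataclass(frozen=True)
class AttributeImportance:
    """Attribute importance and PCA structure of the mean-score matrix."""

    importance: pd.Series  # |r| with day, in [0, 1]
    relevant: pd.Series  # importance > RELEVANCE_CUTOFF
    variance_fractions: np.ndarray  # non-increasing, sums to 1
    loadings: pd.DataFrame  # attributes x components, orthonormal columns


def _panel_day_means(records: pd.DataFrame) -> pd.Series:
    return records.groupby("day")["qi"].mean().sort_index()


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame(
        [
            {"fish_id": r.fish_id, "assessor_id": r.assessor_id, "day": r.day, "qi": r.qi}
            for r in records
        ]
    )


def fit_qi_time(records, max_qi: float | None = None) -> LinearCalibration:
    """Fit panel-mean QI against day on ice by ordinary least squares.

    Parameters
    ----------
    records
        QIRecord iterable or a DataFrame with ``day`` and ``qi`` columns.
        Records are aggregated to per-day panel means before fitting.
    max_qi
        Scheme ceiling.  When given, days whose panel mean lies within
        ``SATURATION_MARGIN`` of the ceiling are excluded from the fit.
    """
    df = _as_frame(records)
    means = _panel_day_means(df)
    if max_qi is not None:
        saturated = means >= (max_qi - SATURATION_MARGIN)
        keep = ~saturated.cummax()  # drop the first saturated day and beyond
        # never drop below the minimum needed for a line with residual df
        if keep.sum() >= 3:
            means = means[keep]
    days = means.index.to_numpy(dtype=float)
    qi = means.to_numpy(dtype=float)
    if len(days) < 3:
        raise ValueError(f"need >=3 distinct sampling days, got {len(days)}")
    if np.ptp(days) == 0:
        raise ValueError("zero variance in day: all records share one sampling day")
    res = stats.linregress(days, qi)
    slope, intercept = float(res.slope), float(res.intercept)
    if slope <= 0:
        warnings.warn(
            f"fitted QI slope {slope:.3g} is not positive; "
            "quality index is expected to rise during spoilage",
            stacklevel=2,
        )
    pred = intercept + slope * days
    resid = qi - pred
    residual_sd = float(np.sqrt(np.sum(resid**2) / max(len(days) - 2, 1)))
    rmse_days = _rmse_days(days, qi, slope, intercept)
    rmse_loo = _rmse_days_loo(days, qi)
    return LinearCalibration(
        slope=slope,
        intercept=intercept,
        r2=float(res.rvalue**2),
        residual_sd=residual_sd,
        n_days=len(days),
        rmse_days=rmse_days,
        rmse_days_loo=rmse_loo,
    )


def _rmse_days(days, qi, slope, intercept) -> float:
    if slope == 0:
        return float("inf")
    pred_day = (qi - intercept) / slope
    return float(np.sqrt(np.mean((pred_day - days) ** 2)))


def _rmse_days_loo(days, qi) -> float:
    """Leave-one-day-out inverse-prediction RMSE."""
    n = len(days)
    if n < 4:
        return float("nan")
    errs = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        res = stats.linregress(days[mask], qi[mask])
        if res.slope == 0:
            return float("inf")
        errs.append((qi[i] - res.intercept) / res.slope - days[i])
    return float(np.sqrt(np.mean(np.square(errs))))


def predict_storage_day(qi: float, cal: LinearCalibration) -> DayEstimate:
    """Invert the calibration line to estimate days on ice from a QI.

    The interval is simple propagation of the day-scale RMSE through a
    t quantile at the calibration's residual degrees of freedom; Fieller-type
    intervals are out of scope and this understates uncertainty far from the
    calibrated range.
    """
    if cal.slope == 0:
        raise ValueError("calibration slope is zero; day is not identifiable")
    point = (qi - cal.intercept) / cal.slope
    df = max(cal.df, 1)
    half = stats.t.ppf(0.975, df) * cal.rmse_days
    clipped = point < 0
    day = max(point, 0.0)
    return DayEstimate(
        day=float(day),
        lower=float(max(point - half, 0.0)),
        upper=float(max(point + half, 0.0)),
        clipped=bool(clipped),
    )


def remaining_shelf_life(
    qi: float, cal: LinearCalibration, shelf_life_days: float
) -> float:
    """Days of shelf life left, given a QI and a total shelf life."""
    if shelf_life_days <= 0:
        raise ValueError("shelf_life_days must be positive")
    est = predict_storage_day(qi, cal)
    return float(max(0.0, shelf_life_days - est.day))


def assessor_performance(
    records, slope_band: tuple[float, float] = (0.8, 1.2)
) -> PanelPerformance:
    """Regress each assessor's per-day mean QI on the panel consensus.

    The consensus for an assessor excludes that assessor's own scores, so a
    lone drifting panelist cannot drag their own reference along.  Assessors
    with fewer than 3 days shared with the rest of the panel are excluded
    with a warning.
    """
    df = _as_frame(records)
    assessors = sorted(df["assessor_id"].unique())
    if len(assessors) < 2:
        raise ValueError("panel performance needs >=2 assessors")
    per = df.groupby(["assessor_id", "day"])["qi"].mean().unstack("day")
    rows = []
    for a in assessors:
        own = per.loc[a].dropna()
        others = per.drop(index=a).mean(axis=0).dropna()
        shared = own.index.intersection(others.index)
        if len(shared) < 3:
            warnings.warn(
                f"assessor {a!r} shares only {len(shared)} days with the panel; excluded",
                stacklevel=2,
            )
            continue
        x = others.loc[shared].to_numpy(dtype=float)
        y = own.loc[shared].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"panel mean constant for assessor {a!r}; excluded", stacklevel=2)
            continue
        res = stats.linregress(x, y)
        rows.append(
            {
                "assessor_id": a,
                "slope": float(res.slope),
                "intercept": float(res.intercept),
                "r2": float(res.rvalue**2),
                "n_days": int(len(shared)),
                "flagged": not (slope_band[0] <= res.slope <= slope_band[1]),
            }
        )
    return PanelPerformance(table=pd.DataFrame(rows), slope_band=slope_band)


def attribute_mean_scores(observations, scheme) -> pd.DataFrame:
    """Day-by-attribute matrix of panel-mean demerit scores."""
    rows = [
        {"day": o.day, **{n: int(o.scores[n]) for n in scheme.parameter_names}}
        for o in observations
    ]
    df = pd.DataFrame(rows)
    return df.groupby("day").mean().sort_index()


def attribute_importance(matrix: pd.DataFrame) -> AttributeImportance:
    """Attribute importance (|r| versus day) plus PCA of the score matrix.

    ``matrix`` is indexed by day with one column per attribute (panel-mean
    scores).  Constant columns get importance 0 and are left out of the
    standardized PCA, with a warning.
    """
    if matrix.shape[0] < 3:
        raise ValueError("need >=3 days for attribute importance")
    if matrix.shape[1] < 2:
        raise ValueError("need >=2 attributes for attribute importance")
    days = matrix.index.to_numpy(dtype=float)
    importance = {}
    varying = []
    for col in matrix.columns:
        y = matrix[col].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            warnings.warn(
                f"attribute {col!r} is constant over days; importance 0, "
                "excluded from PCA standardization",
                stacklevel=2,
            )
            importance[col] = 0.0
            continue
        importance[col] = float(abs(stats.pearsonr(days, y)[0]))
        varying.append(col)
    if len(varying) < 2:
        raise ValueError("need >=2 non-constant attributes for PCA")
    X = matrix[varying].to_numpy(dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    n_comp = min(Z.shape)
    pca = PCA(n_components=n_comp)
    pca.fit(Z)
    frac = pca.explained_variance_ratio_
    frac = frac / frac.sum()  # guard tiny numerical shortfall
    loadings = pd.DataFrame(
        pca.components_.T,
        index=varying,
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )
    imp = pd.Series(importance).reindex(matrix.columns)
    return AttributeImportance(
        importance=imp,
        relevant=imp > RELEVANCE_CUTOFF,
        variance_fractions=frac,
        loadings=loadings,
    )
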