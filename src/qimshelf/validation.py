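"""Analytical validation statistics for the TMA quantification method.

Covers what an AOAC-style single-laboratory validation of a headspace
GC-MS amine assay reports: the (possibly quadratic) calibration function
fitted to replicated standards, a lack-of-fit F-test for the adequacy of
that functional form, detection and quantification limits from the
intercept dispersion, matrix effect by comparison of solvent and
standard-addition slopes, spike recovery, and precision as percent RSD.

Acceptance bands used for the pass/fail flags:

==================  =========
matrix effect       70-125 %
recovery            80-115 %
precision (RSD)     < 15 %
lack of fit         F_exp < F_crit(95 %)
==================  =========
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnalyticalCalibration",
    "LinearityTest",
    "Recovery",
    "PrecisionRSD",
    "MatrixEffect",
    "ValidationReport",
    "fit_analytical_calibration",
    "lack_of_fit_test",
    "lod_loq",
    "matrix_effect",
    "recovery",
    "precision_rsd",
    "compile_validation_report",
    "read_calibration_table",
]

MATRIX_EFFECT_BAND = (70.0, 125.0)
RECOVERY_BAND = (80.0, 115.0)
RSD_LIMIT = 15.0
LOD_MULTIPLIER = 3.3
LOQ_MULTIPLIER = 10.0


@dataclass(frozen=True)
class AnalyticalCalibration:
    """Polynomial calibration y = a*x^2 + b*x + c on replicated standards."""

    concentrations: np.ndarray  # one entry per observation, ug/mL
    signals: np.ndarray
    degree: int
    a: float  # 0.0 when degree == 1
    b: float  # linear coefficient (the "slope" used for LOD/LOQ, matrix effect)
    c: float  # intercept
    r2: float
    sd_intercept: float
    sd_slope: float

    @property
    def levels(self) -> np.ndarray:
        return np.unique(self.concentrations)

    @property
    def n_obs(self) -> int:
        return len(self.concentrations)

    @property
    def n_params(self) -> int:
        return self.degree + 1

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a * x**2 + self.b * x + self.c


@dataclass(frozen=True)
class LinearityTest:
    """Lack-of-fit F-test on replicated calibration data."""

    f_exp: float
    df_lof: int
    df_pe: int
    f_crit_95: float
    accepted: bool


@dataclass(frozen=True)
class MatrixEffect:
    pct: float
    slope_comparison_p: float
    passed: bool


@dataclass(frozen=True)
class Recovery:
    pct: float
    passed: bool


@dataclass(frozen=True)
class PrecisionRSD:
    rsd_pct: float
    passed: bool


@dataclass(frozen=True)
class ValidationReport:
    """Assembled validation summary with per-criterion AOAC flags."""

    linearity: LinearityTest | None
    lod: float | None
    loq: float | None
    matrix: MatrixEffect | None
    recoveries: dict = field(default_factory=dict)  # level label -> Recovery
    repeatability: dict = field(default_factory=dict)  # level label -> PrecisionRSD
    intermediate_precision: dict = field(default_factory=dict)
    aoac_flags: dict = field(default_factory=dict)
    overall: str = "indeterminate"  # pass | fail | indeterminate


def fit_analytical_calibration(
    concentrations, signals, degree: int = 2
) -> AnalyticalCalibration:
    """Least-squares polynomial fit of instrument signal on concentration.

    All replicate points enter individually (no pre-averaging), matching
    how the lack-of-fit decomposition is defined.  Standard errors of the
    intercept and the linear coefficient come from the usual OLS covariance
    sigma^2 (X'X)^-1.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(signals, dtype=float)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and signals must be matching 1-D arrays")
    if np.any(x < 0):
        raise ValueError("concentrations must be non-negative")
    n_levels = len(np.unique(x))
    if n_levels < degree + 2:
        raise ValueError(
            f"degree {degree} calibration needs >={degree + 2} distinct levels, "
            f"got {n_levels}"
        )
    # design columns ordered [x^2, x, 1] so coefficients map to (a, b, c)
    cols = [x**d for d in range(degree, -1, -1)]
    X = np.column_stack(cols)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    pred = X @ coef
    resid = y - pred
    sse = float(resid @ resid)
    ssy = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ssy == 0 else 1.0 - sse / ssy
    dof = len(y) - (degree + 1)
    sigma2 = sse / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    sd = np.sqrt(np.diag(cov))
    if degree == 2:
        a, b, c = (float(v) for v in coef)
        sd_slope, sd_intercept = float(sd[1]), float(sd[2])
    else:
        a = 0.0
        b, c = float(coef[0]), float(coef[1])
        sd_slope, sd_intercept = float(sd[0]), float(sd[1])
    return AnalyticalCalibration(
        concentrations=x,
        signals=y,
        degree=degree,
        a=a,
        b=b,
        c=c,
        r2=float(r2),
        sd_intercept=sd_intercept,
        sd_slope=sd_slope,
    )


def lack_of_fit_test(cal: AnalyticalCalibration, alpha: float = 0.05) -> LinearityTest:
    """Araujo-style lack-of-fit F-test for the calibration function.

    The residual sum of squares splits into pure error (within replicate
    groups) and lack of fit (group means vs the fitted curve):

        F_exp = (SS_lof / df_lof) / (SS_pe / df_pe),
        df_lof = #levels - #model parameters,  df_pe = #obs - #levels.

    The proposed function is adequate when F_exp stays below the 95 %
    F quantile at (df_lof, df_pe).  With six levels in triplicate and a
    straight-line model this is F(4, 12), critical value 3.26.
    """
    x, y = cal.concentrations, cal.signals
    levels = cal.levels
    n_levels = len(levels)
    df_lof = n_levels - cal.n_params
    df_pe = cal.n_obs - n_levels
    if df_pe < 1:
        raise ValueError("lack-of-fit test needs replicated levels (pure error df >= 1)")
    if df_lof < 1:
        raise ValueError(
            f"lack-of-fit df {df_lof} < 1: too few levels for a degree-{cal.degree} model"
        )
    ss_pe = 0.0
    ss_lof = 0.0
    for lv in levels:
        grp = y[x == lv]
        mean = grp.mean()
        ss_pe += float(np.sum((grp - mean) ** 2))
        ss_lof += len(grp) * float((mean - cal.predict(lv)) ** 2)
    f_crit = float(stats.f.ppf(1 - alpha, df_lof, df_pe))
    if ss_pe <= 1e-12 * max(float(np.sum(y**2)), 1.0):
        # replicates numerically identical: pure error undefined; a model
        # that also fits the means exactly is trivially adequate
        f_exp = 0.0 if ss_lof <= 1e-12 * max(float(np.sum(y**2)), 1.0) else math.inf
    else:
        f_exp = (ss_lof / df_lof) / (ss_pe / df_pe)
    return LinearityTest(
        f_exp=float(f_exp),
        df_lof=int(df_lof),
        df_pe=int(df_pe),
        f_crit_95=f_crit,
        accepted=bool(f_exp < f_crit),
    )


def lod_loq(cal: AnalyticalCalibration) -> tuple[float, float]:
    """Detection and quantification limits from the calibration dispersion.

    lod = 3.3 * sd(intercept) / |b|, loq = 10 * sd(intercept) / |b|, with b
    the linear coefficient.  The 3.3/10 multipliers are the ICH convention.
    """
    if cal.b == 0:
        raise ValueError("linear coefficient is zero; LOD/LOQ undefined")
    lod = LOD_MULTIPLIER * cal.sd_intercept / abs(cal.b)
    loq = LOQ_MULTIPLIER * cal.sd_intercept / abs(cal.b)
    return float(lod), float(loq)


def matrix_effect(
    solvent: AnalyticalCalibration, matrix: AnalyticalCalibration
) -> MatrixEffect:
    """Matrix effect as the standard-additions/solvent slope ratio (percent).

    Also runs a two-sided t-test for equality of the linear coefficients
    (Welch-style pooling of the two slope standard errors).  The pass flag
    follows the 70-125 % band on the ratio.
    """
    if solvent.degree != matrix.degree:
        raise ValueError("solvent and matrix calibrations must share the model degree")
    if solvent.b == 0:
        raise ValueError("solvent slope is zero; matrix effect undefined")
    pct = 100.0 * matrix.b / solvent.b
    se = math.hypot(solvent.sd_slope, matrix.sd_slope)
    if se == 0:
        p = 1.0 if math.isclose(solvent.b, matrix.b) else 0.0
    else:
        df = (solvent.n_obs - solvent.n_params) + (matrix.n_obs - matrix.n_params)
        tval = (matrix.b - solvent.b) / se
        p = 2.0 * float(stats.t.sf(abs(tval), df))
    passed = MATRIX_EFFECT_BAND[0] <= pct <= MATRIX_EFFECT_BAND[1]
    return MatrixEffect(pct=float(pct), slope_comparison_p=float(p), passed=bool(passed))


def recovery(measured: float, true_spike: float) -> Recovery:
    """Spike recovery as percent of the true added amount."""
    if true_spike <= 0:
        raise ValueError("true spike must be positive")
    pct = 100.0 * measured / true_spike
    return Recovery(pct=float(pct), passed=bool(RECOVERY_BAND[0] <= pct <= RECOVERY_BAND[1]))


def precision_rsd(replicates) -> PrecisionRSD:
    """Percent relative standard deviation (sample sd, n-1 denominator)."""
    y = np.asarray(replicates, dtype=float)
    if len(y) < 2:
        raise ValueError("precision needs >=2 replicates")
    mean = y.mean()
    if mean == 0:
        raise ValueError("mean of replicates is zero; RSD undefined")
    rsd = 100.0 * y.std(ddof=1) / abs(mean)
    return PrecisionRSD(rsd_pct=float(rsd), passed=bool(rsd < RSD_LIMIT))


def compile_validation_report(
    linearity: LinearityTest | None = None,
    lod: float | None = None,
    loq: float | None = None,
    matrix: MatrixEffect | None = None,
    recoveries: dict | None = None,
    repeatability: dict | None = None,
    intermediate_precision: dict | None = None,
) -> ValidationReport:
    """Assemble component statistics into one report with AOAC flags.

    Overall verdict is ``pass`` iff every provided criterion passes and no
    required component is missing; a missing component leaves the verdict
    ``indeterminate``; any failing flag makes it ``fail``.
    """
    recoveries = dict(recoveries or {})
    repeatability = dict(repeatability or {})
    intermediate_precision = dict(intermediate_precision or {})
    flags: dict[str, bool | None] = {}
    flags["linearity"] = None if linearity is None else linearity.accepted
    flags["lod_loq"] = None if (lod is None or loq is None) else (lod >= 0 and loq >= lod)
    flags["matrix_effect"] = None if matrix is None else matrix.passed
    flags["recovery"] = (
        None if not recoveries else all(r.passed for r in recoveries.values())
    )
    flags["repeatability"] = (
        None if not repeatability else all(r.passed for r in repeatability.values())
    )
    flags["intermediate_precision"] = (
        None
        if not intermediate_precision
        else all(r.passed for r in intermediate_precision.values())
    )
    if any(v is False for v in flags.values()):
        overall = "fail"
    elif any(v is None for v in flags.values()):
        overall = "indeterminate"
    else:
        overall = "pass"
    return ValidationReport(
        linearity=linearity,
        lod=lod,
        loq=loq,
        matrix=matrix,
        recoveries=recoveries,
        repeatability=repeatability,
        intermediate_precision=intermediate_precision,
        aoac_flags=flags,
        overall=overall,
    )


def read_calibration_table(path: str | Path) -> pd.DataFrame:
    """Read replicated calibration data.

    Columns: level_ug_per_ml, replicate, signal, matrix (solvent|sample).
    """
    df = pd.read_csv(path)
    required = {"level_ug_per_ml", "replicate", "signal", "matrix"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"calibration table is missing columns {sorted(missing)}")
    bad = set(df["matrix"].unique()) - {"solvent", "sample"}
    if bad:
        raise ValueError(f"unknown matrix labels {sorted(bad)}")
    return df
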