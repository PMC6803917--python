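"""End-to-end analysis: score -> calibrate -> kinetics -> shelf life.

Thin orchestration over the stage modules so the CLI, the tests and the
reproduction script all run the identical pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from . import calibration as cal_mod
from . import kinetics as kin
from . import shelf_life as sl
from .scheme import QIMScheme, compute_qi, max_qi

__all__ = ["TrialAnalysis", "analyze_trial", "shelf_life_report"]


@dataclass(frozen=True)
class TrialAnalysis:
    qi_records: pd.DataFrame
    calibration: cal_mod.LinearCalibration
    torrymeter_fit: kin.SegmentedFit | None
    growth_fits: dict
    ph: kin.PHTrend | None
    crossings: dict  # assay -> CrossingEstimate (includes "qim")
    estimate: sl.ShelfLifeEstimate


def analyze_trial(
    observations,
    assays: dict[str, kin.AssaySeries],
    scheme: QIMScheme,
    criteria: sl.RejectionCriteria | None = None,
    tma_model: str = "interpolation",
    microbial_window: tuple[float, float] | None = None,
) -> TrialAnalysis:
    """Run the full shelf-life pipeline on one trial's data.

    ``tma_model`` is ``interpolation`` (default) or ``exponential``;
    ``microbial_window`` optionally restricts the log-linear count fits to
    a day range (e.g. past a lag phase).
    """
    criteria = criteria or sl.default_criteria()
    records = pd.DataFrame(
        [
            {"fish_id": r.fish_id, "assessor_id": r.assessor_id, "day": r.day, "qi": r.qi}
            for r in (compute_qi(o, scheme) for o in observations)
        ]
    )
    qi_cal = cal_mod.fit_qi_time(records, max_qi=max_qi(scheme))
    crossings: dict[str, kin.CrossingEstimate] = {}
    sensory = sl.sensory_rejection_day(qi_cal, criteria, max_qi=max_qi(scheme))
    crossings["qim"] = sensory

    torry_fit = None
    if "torrymeter" in assays:
        torry_fit = kin.fit_two_phase(assays["torrymeter"])
        crossings["torrymeter"] = kin.crossing_from_two_phase(
            torry_fit, criteria.threshold("torrymeter")
        )
    growth_fits = {}
    for assay in ("tvc_nt", "tvc_ir", "h2s"):
        if assay in assays:
            fit = kin.fit_growth(assays[assay], window=microbial_window)
            growth_fits[assay] = fit
            crossings[assay] = kin.crossing_from_growth(
                fit, criteria.threshold(assay), assay=assay
            )
    if "tma" in assays:
        if tma_model == "exponential":
            crossings["tma"] = kin.tma_crossing_exponential(
                assays["tma"], criteria.threshold("tma")
            )
        else:
            crossings["tma"] = kin.tma_crossing(assays["tma"], criteria.threshold("tma"))
    ph = kin.ph_trend(assays["ph"]) if "ph" in assays else None

    others = [est for name, est in crossings.items() if name != "qim"]
    estimate = sl.integrate_shelf_life(sensory, others, qi_cal)
    return TrialAnalysis(
        qi_records=records,
        calibration=qi_cal,
        torrymeter_fit=torry_fit,
        growth_fits=growth_fits,
        ph=ph,
        crossings=crossings,
        estimate=estimate,
    )


def _crossing_dict(est: kin.CrossingEstimate) -> dict:
    return {
        "assay": est.assay,
        "threshold": est.threshold,
        "crossing_day": None if math.isnan(est.crossing_day) else est.crossing_day,
        "interval": list(est.interval) if est.interval else None,
        "status": est.status,
    }


def shelf_life_report(analysis: TrialAnalysis) -> dict:
    """JSON-ready report mirroring the per-assay rejection table."""
    cal = analysis.calibration
    report = {
        "calibration": {
            "slope": cal.slope,
            "intercept": cal.intercept,
            "r2": cal.r2,
            "rmse_days": cal.rmse_days,
            "rmse_days_loo": cal.rmse_days_loo,
            "n_days": cal.n_days,
        },
        "crossings": {name: _crossing_dict(c) for name, c in analysis.crossings.items()},
        "shelf_life": {
            "integrated_days": analysis.estimate.integrated_days,
            "uncertainty_days": analysis.estimate.uncertainty_days,
            "consistent": analysis.estimate.consistent,
        },
    }
    if analysis.ph is not None:
        report["ph_trend"] = {
            "slope": analysis.ph.slope,
            "p_value": analysis.ph.p_value,
            "significant": analysis.ph.significant,
        }
    if analysis.torrymeter_fit is not None:
        f = analysis.torrymeter_fit
        report["torrymeter_fit"] = {
            "breakpoint_day": f.breakpoint_day,
            "slope1": f.slope1,
            "slope2": f.slope2,
            "r2_1": f.r2_1,
            "r2_2": f.r2_2,
        }
    report["growth_fits"] = {
        name: {"slope": g.slope, "intercept": g.intercept, "r2": g.r2}
        for name, g in analysis.growth_fits.items()
    }
    return report


def format_rejection_table(analysis: TrialAnalysis, criteria=None) -> str:
    """Human-readable per-assay rejection table."""
    criteria = criteria or sl.default_criteria()
    lines = [
        f"{'Method':<14}{'Criterion':>12}{'Value':>10}{'Rejection day':>16}",
        "-" * 52,
    ]
    for name, est in analysis.crossings.items():
        spec = criteria[name] if name in criteria else None
        direction = spec.direction if spec else ""
        if est.status == "crossed":
            window = f"{est.interval[0]}-{est.interval[1]} ({est.crossing_day:.2f})"
        else:
            window = est.status
        lines.append(
            f"{name:<14}{direction:>12}{est.threshold:>10g}{window:>16}"
        )
    e = analysis.estimate
    lines.append("-" * 52)
    lines.append(
        f"Integrated shelf life: {e.integrated_days:g} +/- {e.uncertainty_days:g} days "
        f"({'consistent' if e.consistent else 'INCONSISTENT'} across assays)"
    )
    return "\n".join(lines)
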