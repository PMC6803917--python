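"""Synthetic ice-storage trials with known ground truth.

Emulates a whole-fish QIM storage trial at 0 +/- 1 degC: a six-assessor
panel scoring three fish per sampling day on the packaged 25-point scheme,
plus the instrumental series (two-phase Torrymeter decay, log-linear
microbial growth with a lagging H2S population, slow-then-fast TMA
accumulation, weak pH drift) and a replicated quadratic analytical
calibration in solvent and in matrix.

The sensory ground truth is ordinal, not a line: each parameter follows a
step schedule of transition days, and the near-linear panel-mean QI
*emerges* from summing nine staggered step functions — the same mechanism
that produces linear QI growth in real trials.  Pooled transitions are
placed at days (k - 1/2) / slope so the latent QI tracks ``slope * day``,
and apportioned to parameters by a largest-deficit rule that interleaves
each parameter's transitions evenly.

Every generator draws from its own child stream of the trial seed, so
adding a generator never perturbs another's draws, and identical
(config, seed) pairs give byte-identical trials.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .kinetics import AssaySeries
from .scheme import QIMScheme, SensoryObservation, default_scheme, max_qi

__all__ = [
    "TrialConfig",
    "SyntheticTrial",
    "default_schedules",
    "generate_panel_scores",
    "generate_assay_series",
    "generate_analytical_calibration",
    "simulate_trial",
    "write_trial",
]

# fixed child-stream indices; append only, never reorder
_STREAMS = {
    "panel": 0,
    "torrymeter": 1,
    "tvc_nt": 2,
    "tvc_ir": 3,
    "h2s": 4,
    "tma": 5,
    "ph": 6,
    "calibration": 7,
}


@dataclass(frozen=True)
class TrialConfig:
    """Study conditions for one synthetic storage trial.

    Defaults encode the trial design and printed trajectory values for
    ice-stored greater amberjack: QI rising ~1.45 points/day from ~0.4,
    Torrymeter falling from 16.8 at -0.809 then -0.375 units/day with the
    phase change near day 11.5, total viable counts growing from 1e3
    cfu/cm2 at 0.45 log10/day with H2S producers about one decade behind
    until day ~9, TMA climbing 5.6 -> 20.7 mg/100 g over 15 days, pH
    drifting 6.4 -> 6.7, and a quadratic instrument response over
    0.1-15 ug/mL in triplicate with a 6 % hotter slope in matrix.
    """

    seed: int = 0
    # sensory panel
    sampling_days: tuple[float, ...] = (0, 2, 4, 7, 9, 12, 15, 17, 20)
    n_fish: int = 3
    n_assessors: int = 6
    score_noise: float = 0.1  # probability an assessor slips +/-1 on a parameter
    qi_slope: float = 1.45  # latent QI points per day
    schedules: dict[str, tuple[float, ...]] | None = None  # derived when None
    # torrymeter two-phase decay
    torry_days: tuple[float, ...] = (1, 2, 4, 5, 7, 9, 10, 11, 12, 13, 14, 15, 18, 20)
    torry_start: float = 16.8
    torry_slope1: float = -0.809
    torry_slope2: float = -0.375
    torry_break: float = 11.5
    torry_sd: float = 0.2
    # microbial growth (log10 cfu/cm2)
    micro_days: tuple[float, ...] = (1, 2, 3, 5, 7, 9, 10, 13, 14, 15)
    micro_intercept: float = 3.0
    micro_slope: float = 0.45
    micro_sd: float = 0.2
    h2s_offset: float = -1.0  # decades below TVC during the lag
    h2s_lag_end: float = 9.0  # offset starts shrinking here ...
    h2s_converge_day: float = 13.0  # ... and is gone here
    # TMA accumulation (mg/100 g)
    tma_days: tuple[float, ...] = (0, 2, 4, 7, 9, 12, 15)
    tma_points: tuple[tuple[float, float], ...] = ((0, 5.6), (7, 9.0), (12, 11.1), (15, 20.7))
    tma_sd: float = 0.5
    # pH drift
    ph_days: tuple[float, ...] = (0, 2, 5, 8, 12, 14, 15, 17, 20)
    ph_start: float = 6.4
    ph_end: float = 6.7
    ph_sd: float = 0.15
    # analytical calibration (signal = a x^2 + b x + c)
    cal_levels: tuple[float, ...] = (0.1, 1.0, 3.0, 6.0, 10.0, 15.0)
    cal_replicates: int = 3
    cal_coef: tuple[float, float, float] = (-0.0108, 1.080, 0.1102)
    cal_rel_sd: float = 0.02  # noise sd proportional to the true signal
    cal_abs_sd: float = 0.01  # plus an absolute floor
    matrix_multiplier: float = 1.06  # matrix slope / solvent slope

    def validate(self, scheme: QIMScheme) -> None:
        if not 0.0 <= self.score_noise <= 0.5:
            raise ValueError("score_noise must lie in [0, 0.5]")
        for name in ("torry_sd", "micro_sd", "tma_sd", "ph_sd", "cal_rel_sd", "cal_abs_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.qi_slope <= 0:
            raise ValueError("qi_slope must be positive")
        sched = self.schedules
        if sched is not None:
            names = set(scheme.parameter_names)
            for pname, days in sched.items():
                if pname not in names:
                    raise ValueError(f"schedule for unknown parameter {pname!r}")
                if list(days) != sorted(days):
                    raise ValueError(f"schedule for {pname!r} is not monotone")
                if len(days) > scheme.parameter(pname).max_score:
                    raise ValueError(
                        f"schedule for {pname!r} has {len(days)} transitions but the "
                        f"parameter maximum is {scheme.parameter(pname).max_score}"
                    )


@dataclass(frozen=True)
class SyntheticTrial:
    observations: tuple[SensoryObservation, ...]
    assays: dict[str, AssaySeries]
    calibration: dict  # {"solvent": {...}, "matrix": {...}}
    ground_truth: dict


def _rng(config: TrialConfig, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(config.seed), spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


def default_schedules(
    scheme: QIMScheme, slope: float
) -> dict[str, tuple[float, ...]]:
    """Evenly interleaved per-parameter transition days.

    The k-th pooled transition (k = 1..max_qi) lands at day (k - 0.5)/slope
    and is handed to the parameter with the largest apportionment deficit,
    so every parameter's own transitions are spread across storage and the
    latent QI staircase tracks ``slope * day``.
    """
    params = scheme.parameters
    total = max_qi(scheme)
    assigned = {p.name: 0 for p in params}
    sched: dict[str, list[float]] = {p.name: [] for p in params}
    for k in range(1, total + 1):
        day = (k - 0.5) / slope
        open_params = [p for p in params if assigned[p.name] < p.max_score]
        best = max(
            open_params,
            key=lambda p: (p.max_score * k / total - assigned[p.name], p.max_score),
        )
        sched[best.name].append(day)
        assigned[best.name] += 1
    return {name: tuple(days) for name, days in sched.items()}


def _latent_score(schedule: tuple[float, ...], day: float) -> int:
    return int(sum(1 for d in schedule if d <= day))


def generate_panel_scores(
    config: TrialConfig, scheme: QIMScheme | None = None
) -> tuple[list[SensoryObservation], dict]:
    """Simulate the panel: step-schedule truth plus assessor slips.

    Each assessor perturbs a parameter's latent score by +/-1 with
    probability ``score_noise`` (clipped to the parameter's range), which
    reproduces the small positive day-0 panel-mean QI seen in practice.
    """
    scheme = scheme or default_scheme()
    config.validate(scheme)
    schedules = config.schedules or default_schedules(scheme, config.qi_slope)
    rng = _rng(config, "panel")
    eps = config.score_noise
    observations: list[SensoryObservation] = []
    for day in config.sampling_days:
        for f in range(config.n_fish):
            fish_id = f"d{day:g}_f{f + 1}"
            for a in range(config.n_assessors):
                scores = {}
                for p in scheme.parameters:
                    latent = _latent_score(schedules[p.name], day)
                    score = latent
                    if eps > 0 and rng.random() < eps:
                        score += int(rng.choice([-1, 1]))
                    scores[p.name] = int(np.clip(score, 0, p.max_score))
                observations.append(
                    SensoryObservation(
                        fish_id=fish_id,
                        assessor_id=f"P{a + 1}",
                        day=float(day),
                        scores=scores,
                    )
                )
    truth = {
        "qi_slope": config.qi_slope,
        "score_noise": eps,
        "schedules": {k: list(v) for k, v in schedules.items()},
    }
    return observations, truth


def _torry_mean(config: TrialConfig, d: np.ndarray) -> np.ndarray:
    b = config.torry_break
    return (
        config.torry_start
        + config.torry_slope1 * np.minimum(d, b)
        + config.torry_slope2 * np.maximum(d - b, 0.0)
    )


def _h2s_lag(config: TrialConfig, d: np.ndarray) -> np.ndarray:
    frac = np.clip(
        (config.h2s_converge_day - d) / (config.h2s_converge_day - config.h2s_lag_end),
        0.0,
        1.0,
    )
    return config.h2s_offset * frac


def _tma_mean(config: TrialConfig, d: np.ndarray) -> np.ndarray:
    pts = np.asarray(config.tma_points, dtype=float)
    return np.interp(d, pts[:, 0], pts[:, 1])


def generate_assay_series(config: TrialConfig, assay: str) -> tuple[AssaySeries, dict]:
    """One instrumental series plus the noiseless parameters behind it."""
    scheme = default_scheme()
    config.validate(scheme)
    rng = _rng(config, assay if assay in _STREAMS else "panel")
    if assay == "torrymeter":
        d = np.asarray(config.torry_days, dtype=float)
        mean = _torry_mean(config, d)
        values = mean + rng.normal(0.0, config.torry_sd, size=len(d))
        truth = {
            "start": config.torry_start,
            "slope1": config.torry_slope1,
            "slope2": config.torry_slope2,
            "breakpoint": config.torry_break,
            "sd": config.torry_sd,
        }
    elif assay in ("tvc_nt", "tvc_ir", "h2s"):
        d = np.asarray(config.micro_days, dtype=float)
        mean = config.micro_intercept + config.micro_slope * d
        if assay == "h2s":
            mean = mean + _h2s_lag(config, d)
        values = mean + rng.normal(0.0, config.micro_sd, size=len(d))
        truth = {
            "intercept": config.micro_intercept,
            "slope": config.micro_slope,
            "sd": config.micro_sd,
            "h2s_offset": config.h2s_offset if assay == "h2s" else 0.0,
        }
    elif assay == "tma":
        d = np.asarray(config.tma_days, dtype=float)
        mean = _tma_mean(config, d)
        values = np.maximum(mean + rng.normal(0.0, config.tma_sd, size=len(d)), 0.0)
        truth = {"control_points": [list(p) for p in config.tma_points], "sd": config.tma_sd}
    elif assay == "ph":
        d = np.asarray(config.ph_days, dtype=float)
        span = max(config.ph_days) - min(config.ph_days)
        mean = config.ph_start + (config.ph_end - config.ph_start) * (d - d[0]) / span
        values = mean + rng.normal(0.0, config.ph_sd, size=len(d))
        truth = {"start": config.ph_start, "end": config.ph_end, "sd": config.ph_sd}
    else:
        raise ValueError(f"unknown assay kind {assay!r}")
    return AssaySeries(assay=assay, times=d, values=values), truth


def generate_analytical_calibration(config: TrialConfig) -> tuple[dict, dict]:
    """Replicated solvent and matrix calibration datasets.

    Signals come from the true polynomial with noise proportional to the
    signal (plus an absolute floor); the matrix dataset multiplies the
    linear coefficient to emulate the matrix effect.
    """
    if len(config.cal_levels) < 2:
        raise ValueError("calibration needs >=2 levels")
    rng = _rng(config, "calibration")
    a, b, c = config.cal_coef
    out = {}
    for label, bb in (("solvent", b), ("matrix", b * config.matrix_multiplier)):
        conc, sig = [], []
        for lv in config.cal_levels:
            true = a * lv**2 + bb * lv + c
            sd = config.cal_rel_sd * abs(true) + config.cal_abs_sd
            for _ in range(config.cal_replicates):
                conc.append(lv)
                sig.append(true + rng.normal(0.0, sd))
        out[label] = {
            "concentrations": np.asarray(conc),
            "signals": np.asarray(sig),
        }
    truth = {
        "coef": list(config.cal_coef),
        "matrix_multiplier": config.matrix_multiplier,
        "rel_sd": config.cal_rel_sd,
        "abs_sd": config.cal_abs_sd,
    }
    return out, truth


def simulate_trial(config: TrialConfig | None = None) -> SyntheticTrial:
    """Generate a full trial (panel + assays + calibration) from one seed."""
    config = config or TrialConfig()
    scheme = default_scheme()
    observations, panel_truth = generate_panel_scores(config, scheme)
    assays = {}
    assay_truth = {}
    for assay in ("torrymeter", "tvc_nt", "tvc_ir", "h2s", "tma", "ph"):
        series, truth = generate_assay_series(config, assay)
        assays[assay] = series
        assay_truth[assay] = truth
    calibration, cal_truth = generate_analytical_calibration(config)
    ground_truth = {
        "seed": config.seed,
        "panel": panel_truth,
        "assays": assay_truth,
        "calibration": cal_truth,
    }
    return SyntheticTrial(
        observations=tuple(observations),
        assays=assays,
        calibration=calibration,
        ground_truth=ground_truth,
    )


def write_trial(trial: SyntheticTrial, outdir: str | Path) -> None:
    """Write a trial as the CSV dialects the analysis stages read."""
    import pandas as pd

    from .kinetics import write_assay_series
    from .scheme import write_observations

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scheme = default_scheme()
    write_observations(trial.observations, scheme, outdir / "observations.csv")
    write_assay_series(trial.assays, outdir / "assays.csv")
    rows = []
    for label, data in trial.calibration.items():
        reps: dict[float, int] = {}
        for conc, sig in zip(data["concentrations"], data["signals"]):
            reps[conc] = reps.get(conc, 0) + 1
            rows.append(
                {
                    "level_ug_per_ml": conc,
                    "replicate": reps[conc],
                    "signal": sig,
                    "matrix": "sample" if label == "matrix" else "solvent",
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "calibration.csv", index=False)
    (outdir / "ground_truth.json").write_text(
        json.dumps(trial.ground_truth, indent=2, default=float), encoding="utf-8"
    )


def config_with(seed: int, **overrides) -> TrialConfig:
    """Default config with a seed and field overrides."""
    return dataclasses.replace(TrialConfig(), seed=seed, **overrides)
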