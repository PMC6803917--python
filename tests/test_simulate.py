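"""Synthetic trial generator: determinism, shapes and parameter recovery."""

import dataclasses
import json

import numpy as np
import pandas as pd
import pytest

from qimshelf import kinetics as kin
from qimshelf import validation as val
from qimshelf.calibration import fit_qi_time
from qimshelf.scheme import compute_qi, default_scheme, max_qi
from qimshelf.simulate import (
    TrialConfig,
    default_schedules,
    generate_analytical_calibration,
    generate_assay_series,
    generate_panel_scores,
    simulate_trial,
    write_trial,
)


def qi_frame(observations, scheme):
    return pd.DataFrame(
        [
            {"fish_id": r.fish_id, "assessor_id": r.assessor_id, "day": r.day, "qi": r.qi}
            for r in (compute_qi(o, scheme) for o in observations)
        ]
    )


class TestSchedules:
    def test_every_parameter_fully_scheduled(self, scheme):
        sched = default_schedules(scheme, 1.45)
        for p in scheme.parameters:
            assert len(sched[p.name]) == p.max_score
            assert list(sched[p.name]) == sorted(sched[p.name])
        total = sum(len(v) for v in sched.values())
        assert total == max_qi(scheme)

    def test_schedule_beyond_attribute_max_rejected(self, scheme):
        cfg = dataclasses.replace(
            TrialConfig(), schedules={"eye_shape": (1.0, 2.0, 3.0)}
        )
        with pytest.raises(ValueError, match="eye_shape"):
            cfg.validate(scheme)


class TestPanel:
    def test_no_noise_means_identical_assessors(self, scheme):
        cfg = dataclasses.replace(TrialConfig(), score_noise=0.0)
        obs, _ = generate_panel_scores(cfg, scheme)
        df = qi_frame(obs, scheme)
        per_assessor = df.groupby(["day", "assessor_id"])["qi"].mean().unstack()
        assert (per_assessor.nunique(axis=1) == 1).all()

    def test_day_beyond_last_transition_saturates(self, scheme):
        cfg = dataclasses.replace(TrialConfig(), score_noise=0.0, sampling_days=(19.0,))
        obs, _ = generate_panel_scores(cfg, scheme)
        df = qi_frame(obs, scheme)
        assert (df["qi"] == max_qi(scheme)).all()

    def test_default_trial_recovers_slope_within_10pct(self, scheme):
        obs, truth = generate_panel_scores(TrialConfig(seed=1), scheme)
        cal = fit_qi_time(qi_frame(obs, scheme), max_qi=max_qi(scheme))
        assert abs(cal.slope - truth["qi_slope"]) / truth["qi_slope"] < 0.10

    def test_slope_recovery_improves_with_replicates(self, scheme):
        # score-noise bias on the fitted slope shrinks as the panel grows
        errs = {}
        for n in (5, 50):
            cfg = dataclasses.replace(TrialConfig(), seed=10, n_fish=n)
            obs, truth = generate_panel_scores(cfg, scheme)
            cal = fit_qi_time(qi_frame(obs, scheme), max_qi=max_qi(scheme))
            errs[n] = abs(cal.slope - truth["qi_slope"])
        assert errs[50] <= errs[5] + 0.05

    def test_median_slope_error_under_5pct(self, scheme):
        errs = []
        for seed in range(1, 51):
            obs, truth = generate_panel_scores(TrialConfig(seed=seed), scheme)
            cal = fit_qi_time(qi_frame(obs, scheme), max_qi=max_qi(scheme))
            errs.append(abs(cal.slope - truth["qi_slope"]) / truth["qi_slope"])
        assert np.median(errs) < 0.05


class TestAssayGenerators:
    def test_noiseless_torrymeter_exact_recovery(self):
        cfg = dataclasses.replace(TrialConfig(), torry_sd=0.0)
        series, truth = generate_assay_series(cfg, "torrymeter")
        fit = kin.fit_two_phase(series)
        assert fit.slope1 == pytest.approx(truth["slope1"], abs=1e-9)
        assert fit.slope2 == pytest.approx(truth["slope2"], abs=1e-9)

    def test_breakpoint_recovery_at_default_noise(self):
        # candidate breakpoints live on the 1-day sampling grid, so the
        # median error cannot beat one grid step at trial-realistic noise
        errs = []
        for seed in range(1, 51):
            series, truth = generate_assay_series(TrialConfig(seed=seed), "torrymeter")
            errs.append(abs(kin.fit_two_phase(series).breakpoint_day - truth["breakpoint"]))
        assert np.median(errs) <= 1.0

    def test_breakpoint_recovery_at_low_noise(self):
        errs = []
        for seed in range(1, 51):
            cfg = dataclasses.replace(TrialConfig(), seed=seed, torry_sd=0.1)
            series, truth = generate_assay_series(cfg, "torrymeter")
            errs.append(abs(kin.fit_two_phase(series).breakpoint_day - truth["breakpoint"]))
        assert np.median(errs) < 1.0

    def test_microbial_crossing_near_truth(self):
        series, truth = generate_assay_series(TrialConfig(seed=4), "tvc_nt")
        est = kin.crossing_from_growth(kin.fit_growth(series), 8.0)
        true_day = (8.0 - truth["intercept"]) / truth["slope"]
        assert est.status == "crossed"
        assert 9 < est.crossing_day < 13
        assert abs(est.crossing_day - true_day) < 2.0

    def test_growth_rate_median_error_under_10pct(self):
        errs = []
        for seed in range(1, 51):
            series, truth = generate_assay_series(TrialConfig(seed=seed), "tvc_nt")
            fit = kin.fit_growth(series)
            errs.append(abs(fit.slope - truth["slope"]) / truth["slope"])
        assert np.median(errs) < 0.10

    def test_h2s_lags_then_converges(self):
        cfg = dataclasses.replace(TrialConfig(), micro_sd=0.0)
        tvc, _ = generate_assay_series(cfg, "tvc_nt")
        h2s, _ = generate_assay_series(cfg, "h2s")
        gap = tvc.values - h2s.values
        early = gap[tvc.times <= 9]
        late = gap[tvc.times >= 13]
        assert np.allclose(early, 1.0)
        assert np.allclose(late, 0.0)

    def test_ph_endpoints_in_expectation(self):
        cfg = dataclasses.replace(TrialConfig(), ph_sd=0.0)
        series, truth = generate_assay_series(cfg, "ph")
        assert series.values[0] == pytest.approx(truth["start"])
        assert series.values[-1] == pytest.approx(truth["end"])

    def test_unknown_assay_kind(self):
        with pytest.raises(ValueError, match="unknown assay"):
            generate_assay_series(TrialConfig(), "turbidity")


class TestAnalyticalCalibrationGenerator:
    def test_noiseless_exact_recovery(self):
        cfg = dataclasses.replace(TrialConfig(), cal_rel_sd=0.0, cal_abs_sd=0.0)
        data, truth = generate_analytical_calibration(cfg)
        cal = val.fit_analytical_calibration(
            data["solvent"]["concentrations"], data["solvent"]["signals"], 2
        )
        assert cal.a == pytest.approx(truth["coef"][0], abs=1e-9)
        assert cal.b == pytest.approx(truth["coef"][1], abs=1e-9)
        assert cal.c == pytest.approx(truth["coef"][2], abs=1e-9)

    def test_matrix_effect_mean_near_106(self):
        pcts = []
        for seed in range(1, 101):
            data, _ = generate_analytical_calibration(TrialConfig(seed=seed))
            sv = val.fit_analytical_calibration(
                data["solvent"]["concentrations"], data["solvent"]["signals"], 2
            )
            mx = val.fit_analytical_calibration(
                data["matrix"]["concentrations"], data["matrix"]["signals"], 2
            )
            pcts.append(val.matrix_effect(sv, mx).pct)
        assert abs(np.mean(pcts) - 106.0) < 2.0

    def test_suppressive_matrix_fails_band(self):
        cfg = dataclasses.replace(TrialConfig(), matrix_multiplier=0.5)
        data, _ = generate_analytical_calibration(cfg)
        sv = val.fit_analytical_calibration(
            data["solvent"]["concentrations"], data["solvent"]["signals"], 2
        )
        mx = val.fit_analytical_calibration(
            data["matrix"]["concentrations"], data["matrix"]["signals"], 2
        )
        assert not val.matrix_effect(sv, mx).passed


class TestTrialBundle:
    def test_same_seed_identical_output(self, tmp_path):
        a = simulate_trial(TrialConfig(seed=5))
        b = simulate_trial(TrialConfig(seed=5))
        assert a.observations == b.observations
        for assay in a.assays:
            assert np.array_equal(a.assays[assay].values, b.assays[assay].values)
        da, db = tmp_path / "a", tmp_path / "b"
        write_trial(a, da)
        write_trial(b, db)
        for name in ("observations.csv", "assays.csv", "calibration.csv", "ground_truth.json"):
            assert (da / name).read_bytes() == (db / name).read_bytes()

    def test_different_seeds_same_truth_different_noise(self):
        a = simulate_trial(TrialConfig(seed=1))
        b = simulate_trial(TrialConfig(seed=2))
        ta = {k: v for k, v in a.ground_truth.items() if k != "seed"}
        tb = {k: v for k, v in b.ground_truth.items() if k != "seed"}
        assert json.dumps(ta, default=float) == json.dumps(tb, default=float)
        assert not np.array_equal(
            a.assays["torrymeter"].values, b.assays["torrymeter"].values
        )

    def test_end_to_end_shelf_life_near_sensory_truth(self, scheme):
        from qimshelf.pipeline import analyze_trial
        from qimshelf.shelf_life import default_criteria

        trial = simulate_trial(TrialConfig(seed=1))
        analysis = analyze_trial(trial.observations, trial.assays, scheme)
        cfg = TrialConfig()
        truth_day = (default_criteria().threshold("qim") - 0.0) / cfg.qi_slope
        assert abs(analysis.estimate.integrated_days - truth_day) <= 1.0
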