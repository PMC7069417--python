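"""Desk-scale orchestration of the full study.

One call runs the whole experiment on a synthetic cohort: generate
athletes and their four sessions, compute graded-test anchors, build
normalized windowed datasets, calibrate the two kinetic models by particle
swarm, train the recurrent regressor, and evaluate every predictor on the
held-out session of each trial.  All randomness derives deterministically
from a single master seed via per-athlete/per-stage seed sequences, so
adding athletes never perturbs existing ones and a rerun with the same
configuration is bit-identical.

Evaluation note: the network can only predict breaths ``n_past+1 .. N`` of
a test session (it needs a full input window), so all predictors are scored
on that same breath subset to keep the comparison fair.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import FitResult, PsoConfig, SessionData, pso_fit
from .evaluation import EvalReport, evaluate_predictor
from .gxt import GxtResult, analyze_gxt, stage_time_for_power
from .kinetics import simulate
from .preprocess import (NormalizationAnchors, TRIAL_SPLITS, align_to_breaths,
                         assemble_trial, filter_invalid_breaths,
                         normalize_channel, normalize_session)
from .regressor import NetworkSpec, predict, train
from .synthetic import (AthleteProfile, NoiseConfig, SESSION_KINDS,
                        make_cohort, make_protocol, sample_power_trace,
                        simulate_breaths)

__all__ = ["ExperimentConfig", "ComparisonReport", "run_experiment",
           "make_table3_like"]

log = logging.getLogger("vo2pipe")

_REST_S = 240.0  # seated rest before each laboratory test
_WARMUP_S = 600.0  # 10-min warm-up at 85 W preceding the protocols


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything that determines an experiment run."""

    n_athletes: int = 2
    master_seed: int = 0
    trials: tuple[int, ...] = (1, 2)
    models: tuple[str, ...] = ("m1", "m2", "rnn")
    epochs: int = 20
    batch_size: int = 10
    n_past: int = 70
    learning_rate: float = 0.05
    pso_iterations: int = 250
    swarm_size: int = 40
    noise: NoiseConfig = NoiseConfig()
    trace_dt: float = 1.0
    trace_noise_sd: float = 2.0
    outdir: str | None = None

    def content_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir")
        return hashlib.md5(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class ComparisonReport:
    """Per (trial, model, athlete) evaluation results; failed cells carry
    their reason instead of silently disappearing."""

    cells: dict[tuple[int, str, int], EvalReport] = field(default_factory=dict)
    failures: dict[tuple[int, str, int], str] = field(default_factory=dict)
    config: ExperimentConfig | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (trial, model, athlete), rep in sorted(self.cells.items()):
            rows.append({
                "trial": trial, "model": model, "athlete": athlete,
                "mae_pct": rep.residuals.mae_pct,
                "rmse_pct": rep.residuals.rmse_pct,
                "r": rep.residuals.pearson_r,
                "r2": rep.residuals.r_squared,
                "bias_pct": rep.bland_altman.bias_pct,
                "loa95_pct": rep.bland_altman.loa95_pct,
                "ci95_pct": rep.bland_altman.ci95_halfwidth_pct,
                "mae_abs": rep.residuals.mae_abs,
                "rmse_abs": rep.residuals.rmse_abs,
                "bias_abs": rep.bland_altman.bias_abs,
                "frac_acf_outside": rep.acf.frac_outside,
                "n": rep.n,
            })
        return pd.DataFrame(rows)


def _sub_seed(master: int, *key: int) -> int:
    """Deterministic child seed; stable under cohort extension."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=key)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


_STAGE = {"trace": 1, "breaths": 2, "fit_m1": 3, "fit_m2": 4, "rnn": 5}


def _simulate_athlete(profile: AthleteProfile, cfg: ExperimentConfig,
                      athlete_idx: int):
    """Generate the four sessions of one athlete: (trace, cleaned breaths)."""
    sessions = {}
    for kind_idx, kind in enumerate(SESSION_KINDS):
        if kind == "WINGATE":
            protocol = make_protocol(kind, profile)
        else:
            protocol = make_protocol(kind, profile, rest_s=_REST_S,
                                     warmup_s=_WARMUP_S)
        trace = sample_power_trace(
            protocol, dt=cfg.trace_dt, noise_sd=cfg.trace_noise_sd,
            seed=_sub_seed(cfg.master_seed, athlete_idx, _STAGE["trace"], kind_idx))
        series = simulate_breaths(
            trace, profile, cfg.noise,
            seed=_sub_seed(cfg.master_seed, athlete_idx, _STAGE["breaths"], kind_idx))
        series, n_removed = filter_invalid_breaths(series)
        if n_removed:
            log.debug("athlete %d %s: removed %d invalid breaths",
                      athlete_idx, kind, n_removed)
        sessions[kind] = (trace, series)
    return sessions


def _anchors_from_gxt(gxt: GxtResult, profile: AthleteProfile) -> NormalizationAnchors:
    return NormalizationAnchors(
        vo2=(gxt.vo2r, gxt.vo2max),
        rf=(gxt.rf_rest, gxt.rf_max),
        power=(0.0, gxt.ppo),
        cadence=(0.0, profile.cadence_max),
        hr=(profile.hr_rest, profile.hr_max),
    )


def run_experiment(config: ExperimentConfig) -> ComparisonReport:
    """Execute the full study for one configuration."""
    cfg = config
    report = ComparisonReport(config=cfg)
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    cohort = make_cohort(cfg.n_athletes, seed=cfg.master_seed)

    for a_idx, profile in enumerate(cohort):
        try:
            sessions = _simulate_athlete(profile, cfg, a_idx)
            gxt_trace, gxt_series = sessions["GXT"]
            gxt = analyze_gxt(
                gxt_series,
                vt1_time_s=stage_time_for_power(profile.p_vt1),
                vt2_time_s=stage_time_for_power(profile.p_vt2),
                rest_s=_REST_S,
                test_start_s=gxt_series.t[0] + _REST_S + _WARMUP_S)
            anchors = _anchors_from_gxt(gxt, profile)

            norm_sessions = {}
            abs_sessions = {}
            for kind, (trace, series) in sessions.items():
                power_b, cad_b = align_to_breaths(trace, series.t)
                channels, vo2n = normalize_session(series, power_b, cad_b,
                                                   anchors)
                norm_sessions[kind] = (channels, vo2n)
                abs_sessions[kind] = SessionData(
                    power=power_b, times=series.t, vo2=series.vo2,
                    vo2r=gxt.vo2r, vo2max=gxt.vo2max)
        except Exception as exc:  # athlete-level failure hits all cells
            for trial in cfg.trials:
                for model in cfg.models:
                    report.failures[(trial, model, a_idx)] = repr(exc)
            log.warning("athlete %d failed: %r", a_idx, exc)
            continue

        for trial in cfg.trials:
            split = TRIAL_SPLITS[trial]
            test_kind = split.test_sessions[0]
            _, test_vo2n = norm_sessions[test_kind]
            measured = test_vo2n[cfg.n_past:]
            test_abs = abs_sessions[test_kind]
            train_abs = [abs_sessions[k] for k in split.train_sessions]

            for model in cfg.models:
                key = (trial, model, a_idx)
                try:
                    if model in ("m1", "m2"):
                        fit = _fit_model(model, train_abs, cfg, a_idx, trial,
                                         outdir)
                        pred_abs = simulate(
                            model, fit.params, test_abs.power, test_abs.times,
                            vo2r=gxt.vo2r, vo2max=gxt.vo2max)
                        pred = normalize_channel(pred_abs, anchors.vo2)
                        pred = pred[cfg.n_past:]
                    elif model == "rnn":
                        train_ds, test_ds = assemble_trial(
                            norm_sessions, trial, n_past=cfg.n_past)
                        spec = NetworkSpec(
                            n_past=cfg.n_past, epochs=cfg.epochs,
                            batch_size=cfg.batch_size,
                            learning_rate=cfg.learning_rate)
                        net, _ = train(spec, train_ds,
                                       seed=_sub_seed(cfg.master_seed, a_idx,
                                                      _STAGE["rnn"], trial))
                        pred = predict(net, test_ds.X)
                    else:
                        raise ValueError(f"unknown model {model!r}")
                    report.cells[key] = evaluate_predictor(
                        measured, pred, vo2max=gxt.vo2max, vo2r=gxt.vo2r)
                except Exception as exc:
                    report.failures[key] = repr(exc)
                    log.warning("cell %s failed: %r", key, exc)

    if outdir:
        frame = report.to_frame()
        frame.to_csv(outdir / f"report_{cfg.content_hash()}.csv", index=False)
        make_table3_like(report).to_csv(
            outdir / f"summary_{cfg.content_hash()}.csv", index=False)
    return report


def _fit_model(model: str, train_abs: list[SessionData],
               cfg: ExperimentConfig, a_idx: int, trial: int,
               outdir: Path | None) -> FitResult:
    """PSO calibration with an on-disk cache keyed by the config hash."""
    seed = _sub_seed(cfg.master_seed, a_idx, _STAGE[f"fit_{model}"], trial)
    cache = None
    if outdir:
        cache = outdir / f"fit_{model}_a{a_idx}_t{trial}_{cfg.content_hash()}.json"
        if cache.exists():
            d = json.loads(cache.read_text())
            from .calibration import _vector_to_params  # local: cache decode
            return FitResult(params=_vector_to_params(model, np.array(d["x"])),
                             sse=d["sse"], convergence=np.array(d["trace"]),
                             model_id=model)
    fit = pso_fit(model, train_abs,
                  PsoConfig(n_iterations=cfg.pso_iterations,
                            swarm_size=cfg.swarm_size, seed=seed))
    if cache:
        from .calibration import _params_to_vector
        cache.write_text(json.dumps({
            "x": _params_to_vector(fit.params).tolist(),
            "sse": fit.sse, "trace": fit.convergence.tolist()}))
    return fit


def _mean_sd(values: pd.Series) -> str:
    if len(values) == 1:
        return f"{values.iloc[0]:.2f}"
    return f"{values.mean():.2f} ({values.std(ddof=1):.2f})"


def make_table3_like(report: ComparisonReport) -> pd.DataFrame:
    """Group summary table: one row per (trial, model), cells ``mean (SD)``
    across athletes, error metrics in %VO2MAX."""
    frame = report.to_frame()
    cols = ["Trial", "Model", "MAE", "RMSE", "r", "R2", "Bias", "LA95", "CI95"]
    if frame.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    for (trial, model), grp in frame.groupby(["trial", "model"]):
        rows.append({
            "Trial": trial, "Model": model,
            "MAE": _mean_sd(grp["mae_pct"]),
            "RMSE": _mean_sd(grp["rmse_pct"]),
            "r": _mean_sd(grp["r"]),
            "R2": _mean_sd(grp["r2"]),
            "Bias": _mean_sd(grp["bias_pct"]),
            "LA95": _mean_sd(grp["loa95_pct"]),
            "CI95": _mean_sd(grp["ci95_pct"]),
        })
    out = pd.DataFrame(rows, columns=cols)
    for key, reason in sorted(report.failures.items()):
        out = pd.concat([out, pd.DataFrame([{
            "Trial": key[0], "Model": key[1],
            "MAE": f"FAILED(athlete {key[2]}): {reason}"}])],
            ignore_index=True)
    return out
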