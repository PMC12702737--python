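"""End-to-end pipeline: simulate -> features -> affect scoring -> stats ->
regression -> model comparison -> payoff simulation -> report.

One global seed drives every stochastic stage through stage-name-derived
sub-seeds (CRC32 of the stage name XOR the global seed), so inserting or
toggling a stage never reshuffles the randomness of unrelated stages, and an
identical configuration reproduces the report bit-for-bit.
"""

from __future__ import annotations

import time
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from . import eeg, io, npstats, panas, regression, synthetic
from .exceptions import ConfigError
from .payoff import AscentConfig, PayoffModel, ascend, payoff_surface

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "DEFAULT_STAGES"]

DEFAULT_STAGES = ("simulate_data", "features", "panas", "stats", "regress",
                  "compare", "simulate_payoff")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage sub-seed from the global seed and the stage name."""
    return (int(global_seed) ^ zlib.crc32(stage.encode("utf-8"))) % (2 ** 31)


@dataclass
class PipelineConfig:
    generative: synthetic.GenerativeConfig = field(
        default_factory=synthetic.default_generative_config)
    stages: Tuple[str, ...] = DEFAULT_STAGES
    shift_mode: str = "net"
    n_boot: int = 1000
    ci_level: float = 0.95
    folds: int = 5
    repeats: int = 20
    payoff_mode: str = "net"
    ascent: AscentConfig = field(default_factory=AscentConfig)
    eeg_duration: float = 6.0
    seed: int = 42
    log_level: str = "INFO"

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in DEFAULT_STAGES]
        if unknown:
            raise ConfigError(f"unknown stage(s): {unknown}")
        self.generative.validate()


def run_pipeline(config: PipelineConfig, outdir: Optional[str] = None) -> dict:
    """Run the enabled stages in dependency order and return the run report.

    If ``outdir`` is given, the cohort CSV, payoff trajectory/surfaces and
    the report JSON are written there.
    """
    config.validate()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report = {"config_hash": io.config_hash(config), "seed": config.seed,
              "stages": {}, "versions": _versions()}

    cohort_frame = None
    fits = {}

    def stage(name):
        return name in config.stages

    t0 = time.perf_counter()
    if stage("simulate_data"):
        gen = replace(config.generative,
                      seed=stage_seed(config.seed, "simulate_data"))
        cohort = synthetic.generate_cohort(gen)
        cohort_frame = cohort.to_frame()
        if out is not None:
            io.write_cohort(cohort_frame, out / "cohort.csv")
        report["stages"]["simulate_data"] = {
            "n_participants": len(cohort_frame),
            "clip_events": cohort.clip_events,
            "seed": gen.seed,
            "wall_s": time.perf_counter() - t0,
        }

    if stage("features"):
        t = time.perf_counter()
        seed = stage_seed(config.seed, "features")
        pre, post = synthetic.generate_eeg_pair(
            duration=config.eeg_duration, theta_multiplier=1.5,
            gamma_multiplier=1.2, seed=seed)
        scores = eeg.change_scores(pre, post)
        report["stages"]["features"] = {
            "theta_change": scores.theta_change,
            "gamma_change": scores.gamma_change,
            "seed": seed,
            "wall_s": time.perf_counter() - t,
        }

    if stage("panas") and cohort_frame is not None:
        t = time.perf_counter()
        if config.generative.shift_mode == "derived":
            cohort_frame = panas.derive_affect_columns(
                cohort_frame, shift_mode=config.shift_mode)
        report["stages"]["panas"] = {
            "shift_mode": config.shift_mode
            if config.generative.shift_mode == "derived" else "latent",
            "wall_s": time.perf_counter() - t,
        }

    if stage("stats") and cohort_frame is not None:
        t = time.perf_counter()
        seed = stage_seed(config.seed, "stats")
        results = {}
        for col in ("theta_change", "gamma_change",
                    "delta_positive", "delta_negative"):
            tr, flag = npstats.shapiro_wilk_gate(cohort_frame[col])
            results[f"shapiro_{col}"] = {"result": tr, "normal": flag}
        pairs = [("theta_change", "delta_negative"),
                 ("gamma_change", "delta_positive"),
                 ("affective_shift", "delta_positive"),
                 ("affective_shift", "delta_negative")]
        for a, b in pairs:
            results[f"spearman_{a}__{b}"] = npstats.spearman_rho(
                cohort_frame[a], cohort_frame[b])
        for pre_c, post_c in (("pa_pre", "pa_post"), ("na_pre", "na_post")):
            results[f"mann_whitney_{pre_c}__{post_c}"] = npstats.mann_whitney_u(
                cohort_frame[post_c], cohort_frame[pre_c])
        boots = {}
        for col in ("delta_positive", "delta_negative"):
            boots[f"mean_{col}"] = npstats.bootstrap_ci(
                cohort_frame[col].to_numpy(), np.mean,
                n_resamples=config.n_boot, level=config.ci_level, seed=seed)
        report["stages"]["stats"] = {
            "tests": results, "bootstrap": boots,
            "n_tests": len(results), "seed": seed,
            "wall_s": time.perf_counter() - t,
        }

    if stage("regress") and cohort_frame is not None:
        t = time.perf_counter()
        seed = stage_seed(config.seed, "regress")
        block = {}
        for outcome in ("delta_positive", "delta_negative"):
            res = regression.AffectRegressionModel(
                cohort_frame, outcome=outcome).fit()
            fits[outcome] = res
            table = res.bootstrap_ci(n_resamples=config.n_boot,
                                     level=config.ci_level, seed=seed)
            block[outcome] = {
                "params": res.params, "rsquared": res.rsquared,
                "resid_sd": res.resid_sd, "bootstrap": table,
            }
        block["mediation"] = {
            "theta__delta_negative": regression.mediation_indirect(
                cohort_frame, "theta_change", "delta_negative",
                n_boot=config.n_boot, seed=seed),
            "gamma__delta_positive": regression.mediation_indirect(
                cohort_frame, "gamma_change", "delta_positive",
                n_boot=config.n_boot, seed=seed),
        }
        block["seed"] = seed
        block["wall_s"] = time.perf_counter() - t
        report["stages"]["regress"] = block

    if stage("compare") and cohort_frame is not None:
        t = time.perf_counter()
        seed = stage_seed(config.seed, "compare")
        comp = regression.compare_models(cohort_frame, folds=config.folds,
                                         repeats=config.repeats, seed=seed)
        report["stages"]["compare"] = {"comparison": comp, "seed": seed,
                                       "wall_s": time.perf_counter() - t}

    if stage("simulate_payoff"):
        t = time.perf_counter()
        if fits and cohort_frame is not None:
            model = PayoffModel.from_cohort(
                cohort_frame,
                coef_positive=fits["delta_positive"].params.to_numpy(),
                coef_negative=fits["delta_negative"].params.to_numpy(),
                payoff_mode=config.payoff_mode)
        else:
            model = PayoffModel.from_config(
                config.generative, payoff_mode=config.payoff_mode)
        traj = ascend(model, config.ascent)
        if out is not None:
            traj.to_frame().to_csv(out / "trajectory.csv", index=False)
            grid = np.linspace(model.bounds[0, 0], model.bounds[0, 1], 25)
            for shift in (10.0, 20.0):
                surface = payoff_surface(model, shift, grid, grid)
                np.savetxt(out / f"surface_shift{int(shift)}.csv",
                           surface, delimiter=",")
        report["stages"]["simulate_payoff"] = {
            "converged": traj.converged,
            "iterations": traj.iterations,
            "stop_reason": traj.stop_reason,
            "final_payoff": float(traj.payoffs[-1]),
            "final_point_std": traj.states_std[-1],
            "wall_s": time.perf_counter() - t,
        }

    report["wall_s_total"] = time.perf_counter() - t0
    if out is not None:
        io.write_json(report, out / "report.json")
    return report


def _versions() -> dict:
    import pandas
    import scipy
    import statsmodels

    from . import __version__

    return {"neuroaffect": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pandas.__version__,
            "statsmodels": statsmodels.__version__}
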