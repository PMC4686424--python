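"""Canned simulation studies: parameter recovery and model recovery.

These are the package's headline self-checks: simulate a task design at
the canonical parameter regimes, refit blind with the full protocol,
and compare the estimates with the generating values.  The test suite
and the acceptance script both run them, so the problem sizes here are
the single source of truth for those studies (chosen for single-CPU
runs; all sizes scale up for tighter recovery at proportional cost).
"""
from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from .cohort import cohort_weights
from .fitting import FitConfig, FitResult, run_fit
from .models import simulate_dataset, simulate_go_batch
from .params import ModulationSpec, ProcessParams, SimConfig, TaskDesign
from .presets import PROACTIVE_PARAMS, REACTIVE_PARAMS, proactive_params_by_cue
from .stats import summarize

__all__ = [
    "reactive_recovery_config",
    "proactive_recovery_config",
    "model_recovery_config",
    "simulate_reactive_study_data",
    "recover_reactive_dpm",
    "recover_proactive",
    "model_recovery_study",
    "first_passage_check",
]

#: Recovery study data sizes.  Large samples (well beyond what a human
#: session yields) are deliberate: the displacement of the cost minimum
#: along the model's trade-off valley scales with the observation noise,
#: so the data floor is pushed below the simulation-side resolution.
REACTIVE_DATA = dict(n_go=100_000, n_stop_per_ssd=20_000)
PROACTIVE_DATA = dict(n_per_cue=100_000)


def reactive_recovery_config(seed: int, stage_iters=(10, 8, 8)) -> FitConfig:
    return FitConfig(
        n_sim_per_eval=5_000,
        de_popsize=6,
        de_maxiter=25,
        basin_max_iter=6,
        basin_fail_limit=4,
        basin_local_maxfev=20,
        polish_maxfev=300,
        refine_ladder=(12_000, 50_000, 120_000),
        refine_stage_iters=tuple(stage_iters),
        seed=seed,
    )


def proactive_recovery_config(seed: int, stage_iters=(10, 8, 8)) -> FitConfig:
    return FitConfig(
        n_sim_per_eval=3_000,
        de_popsize=6,
        de_maxiter=25,
        basin_max_iter=6,
        basin_fail_limit=4,
        basin_local_maxfev=20,
        polish_maxfev=300,
        cond_basin_max_iter=8,
        cond_basin_fail_limit=5,
        refine_ladder=(12_000, 40_000, 120_000),
        refine_stage_iters=tuple(stage_iters),
        seed=seed,
    )


def model_recovery_config(seed: int) -> FitConfig:
    return FitConfig(
        n_sim_per_eval=2_500,
        de_popsize=6,
        de_maxiter=18,
        basin_max_iter=4,
        basin_fail_limit=3,
        basin_local_maxfev=15,
        polish_maxfev=200,
        # a light refinement ladder so every candidate model reaches its
        # own cost floor before the AIC comparison
        refine_ladder=(8_000, 20_000),
        refine_stage_iters=(8, 6),
        refine_fd=(0.02, 0.01),
        seed=seed,
    )


def _seeds(seed: int, n: int):
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def simulate_reactive_study_data(
    truth: ProcessParams, seed: int, n_go: int, n_stop_per_ssd: int, model="dpm"
):
    design = TaskDesign.reactive()
    spec = ModulationSpec(model_kind=model, free_params=(), conditions=("pooled",))
    cfg = SimConfig(deadline=design.deadline, n_trials=n_go)
    table = simulate_dataset(
        spec, design, {"pooled": truth}, cfg, seed=seed,
        n_go=n_go, n_stop_per_ssd=n_stop_per_ssd,
    )
    obs = {"pooled": summarize(table, design)}
    return design, spec, obs, cohort_weights(table, design)


def recover_reactive_dpm(
    seed: int,
    truth: Optional[ProcessParams] = None,
    stage_iters=(10, 8, 8),
) -> Dict:
    """Simulate the reactive design at the canonical DPM parameters and
    refit all five parameters blind with the single-context cost."""
    truth = truth or REACTIVE_PARAMS["dpm"]
    dseed, fseed = _seeds(seed, 2)
    design, spec, obs, weights = simulate_reactive_study_data(
        truth, dseed, **REACTIVE_DATA
    )
    cfg = reactive_recovery_config(fseed, stage_iters=stage_iters)
    result = run_fit(spec, obs, design, cfg, weights)
    est = result.params_by_condition["pooled"]
    rel = {
        name: abs(getattr(est, name) - getattr(truth, name)) / getattr(truth, name)
        for name in ("a", "tr", "v_e", "v_b", "xb")
    }
    return {"truth": truth, "estimate": est, "rel_err": rel, "result": result}


def recover_proactive(
    modulation: str, seed: int, stage_iters=(10, 8, 8)
) -> Dict:
    """Simulate the proactive design under one modulation model and refit
    the same model (six condition-wise free parameters)."""
    design = TaskDesign.proactive()
    conds = tuple(f"p{int(c * 100)}" for c in design.cues)
    free = PROACTIVE_PARAMS[modulation]["free"]
    free = free if isinstance(free, tuple) else (free,)
    spec = ModulationSpec(model_kind="dpm", free_params=free, conditions=conds)
    params = dict(zip(conds, proactive_params_by_cue(modulation)))
    dseed, fseed = _seeds(seed, 2)
    cfg_sim = SimConfig(deadline=design.deadline, n_trials=PROACTIVE_DATA["n_per_cue"])
    table = simulate_dataset(spec, design, params, cfg_sim, seed=dseed)
    obs = summarize(table, design)
    weights = cohort_weights(table, design)
    cfg = proactive_recovery_config(fseed, stage_iters=stage_iters)
    result = run_fit(spec, obs, design, cfg, weights)
    out = {"truth": params, "result": result, "conditions": conds}
    for pname in free:
        out[pname] = {
            "truth": [getattr(params[c], pname) for c in conds],
            "estimate": [
                getattr(result.params_by_condition[c], pname) for c in conds
            ],
        }
    return out


def model_recovery_study(seed: int, n_rep: int = 3) -> Dict:
    """Fit all three race models to DPM-generated reactive data and count
    how often the DPM attains the lowest AIC."""
    seeds = _seeds(seed, 2 * n_rep)
    wins = 0
    details = []
    for rep in range(n_rep):
        design, _, obs, weights = simulate_reactive_study_data(
            REACTIVE_PARAMS["dpm"], seeds[2 * rep], n_go=4_000, n_stop_per_ssd=800
        )
        aics = {}
        for model in ("dpm", "independent", "interactive"):
            spec = ModulationSpec(
                model_kind=model, free_params=(), conditions=("pooled",)
            )
            res = run_fit(
                spec, obs, design, model_recovery_config(seeds[2 * rep + 1]), weights
            )
            aics[model] = res.aic
        details.append(aics)
        wins += min(aics, key=aics.get) == "dpm"
    return {"wins": wins, "n_rep": n_rep, "aics": details}


def first_passage_check(seed: int) -> Dict:
    """Simulated first-passage mean/variance vs the inverse-Gaussian
    closed forms (no gain, no effective deadline), chunked fine-step
    integration."""
    a, v, sigma = 0.5, 1.0, 0.1
    p = ProcessParams(a=a, tr=0.0, v_e=v, sigma=sigma)
    cfg = SimConfig(dt=5e-5, deadline=0.9)
    rng = np.random.default_rng(seed)
    rts = []
    for _ in range(50):
        z = rng.standard_normal((1_000, cfg.n_steps))
        rts.append(simulate_go_batch(p, cfg, 1_000, noise=z).rts)
    rts = np.concatenate(rts)
    return {
        "mean": float(rts.mean()),
        "var": float(rts.var(ddof=1)),
        "mean_theory": a / v,
        "var_theory": a * sigma**2 / v**3,
        "n": int(rts.size),
    }
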