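"""Model-predicted BOLD magnitudes from the execution process.

The proxy for the trial-evoked hemodynamic response is the cumulative
sum (area under the curve) of the execution process over its active
span: responded trials integrate up to the boundary crossing (the
process terminates there), sub-threshold trials up to the deadline.
The AUC jointly encodes time-to-threshold and distance-to-threshold,
which is what the magnitude of accumulation-related BOLD activity is
taken to track.  No hemodynamic convolution is applied.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .diffusion import Trajectory
from .models import simulate_go_batch
from .params import ProcessParams, SimConfig, TaskDesign

__all__ = ["BoldPrediction", "trial_auc", "predict_bold"]

#: Cue bins mirroring the fMRI condition pooling: executed ("go")
#: responses pooled over lower go-probability cues (<= 60%), withheld
#: ("no-go") outcomes pooled over higher cues (>= 40%).
GO_POOL_MAX_CUE = 0.6
NOGO_POOL_MIN_CUE = 0.4


@dataclass(frozen=True)
class BoldPrediction:
    """Mean execution-process AUC for one cue (or pooled bin) and outcome."""

    condition: str
    outcome: str  # "go" | "no-go"
    mean_auc: float
    n_trials: int


def trial_auc(trajectory: Trajectory, dt: Optional[float] = None) -> float:
    """Cumulative sum of theta_e times dt over the simulated path."""
    if dt is None:
        dt = trajectory.dt
    return float(np.sum(trajectory.theta_e) * dt)


def predict_bold(
    params_by_cue: Sequence[ProcessParams],
    design: TaskDesign,
    n: int = 100,
    seed: int = 0,
    dt: float = 0.001,
) -> List[BoldPrediction]:
    """Per-cue, per-outcome mean execution AUC plus the two pooled bins.

    Simulates ``n`` proactive trials per go-probability cue; each trial's
    AUC is the cumulative sum of theta_e up to its termination.  Bins
    with no trials of an outcome are absent from the result (not zero).
    """
    if design.kind != "proactive":
        raise ValueError("BOLD predictions are defined for the proactive design")
    if len(params_by_cue) != len(design.cues):
        raise ValueError("need one parameter set per cue")
    cfg = SimConfig(dt=dt, deadline=design.deadline)
    ss = np.random.SeedSequence(seed)
    preds: List[BoldPrediction] = []
    go_pool, nogo_pool = [], []
    for cue, params, cseed in zip(design.cues, params_by_cue, ss.spawn(len(design.cues))):
        batch = simulate_go_batch(params, cfg, n, seed=cseed)
        label = f"cue={cue:.0%}"
        for outcome, mask in (("go", batch.responded), ("no-go", ~batch.responded)):
            if mask.any():
                preds.append(
                    BoldPrediction(
                        condition=label,
                        outcome=outcome,
                        mean_auc=float(batch.auc[mask].mean()),
                        n_trials=int(mask.sum()),
                    )
                )
        if cue <= GO_POOL_MAX_CUE:
            go_pool.append(batch.auc[batch.responded])
        if cue >= NOGO_POOL_MIN_CUE:
            nogo_pool.append(batch.auc[~batch.responded])
    for label, pool, outcome in (
        ("pooled cue<=60%", go_pool, "go"),
        ("pooled cue>=40%", nogo_pool, "no-go"),
    ):
        vals = np.concatenate(pool) if pool else np.empty(0)
        if vals.size:
            preds.append(
                BoldPrediction(
                    condition=label,
                    outcome=outcome,
                    mean_auc=float(vals.mean()),
                    n_trials=int(vals.size),
                )
            )
    return preds
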