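"""Trial generators for the three stopping models and dataset simulation.

Three accounts of how a planned response is cancelled:

* **Dependent process model (DPM)** — at the stop-signal delay a braking
  accumulator is initialised at the *current state* of the execution
  process and drifts (rate -v_b, no urgency gain) toward 0; hitting 0
  cancels the response.  The brake inherits whatever head start the
  execution process has built up, so stopping gets harder the closer the
  execution process is to threshold.
* **Independent race** — the brake starts from 0 at the stop-signal delay
  and races (rate +v_b) to the same boundary a; go and stop processes
  share no state.
* **Interactive race** — after a registration delay sso, an accumulating
  braking signal is subtracted from the execution signal; the response
  requires the *net* signal to reach a.

On a go trial only the execution process runs; a proactive "no-go" is
simply a failure to reach the boundary before the deadline.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from . import _kernels
from .diffusion import gain_profile
from .params import ModulationSpec, ProcessParams, SimConfig, TaskDesign

__all__ = [
    "TrialOutcome",
    "BatchResult",
    "simulate_go_batch",
    "simulate_stop_batch",
    "simulate_go_trial",
    "simulate_dpm_stop_trial",
    "simulate_independent_stop_trial",
    "simulate_interactive_stop_trial",
    "simulate_dataset",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = ["subject", "condition", "task", "trial_type", "ssd", "cue", "response", "rt"]


@dataclass(frozen=True)
class TrialOutcome:
    """Outcome of a single simulated trial."""

    responded: bool
    rt: Optional[float] = None
    ssd: Optional[float] = None
    cue: Optional[float] = None

    def __post_init__(self) -> None:
        if self.responded and self.rt is None:
            raise ValueError("responded trials must carry an rt")
        if not self.responded and self.rt is not None:
            raise ValueError("non-responded trials must not carry an rt")


@dataclass
class BatchResult:
    """Vectorised outcomes for a batch of identically-configured trials."""

    responded: np.ndarray  # bool (n,)
    rt: np.ndarray  # float (n,), NaN where no response
    auc: np.ndarray  # float (n,), cumulative-sum of the (net) process * dt

    @property
    def n(self) -> int:
        return len(self.responded)

    @property
    def p_respond(self) -> float:
        return float(self.responded.mean()) if self.n else float("nan")

    @property
    def rts(self) -> np.ndarray:
        return self.rt[self.responded]


def _noise(seed, n: int, n_steps: int, streams: int = 1):
    """Standard-normal increment arrays with per-trial rows tied to a
    counter-based (Philox) stream, so trial i is reproducible regardless
    of batch composition order."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    gens = [np.random.Generator(np.random.Philox(c)) for c in ss.spawn(streams)]
    return [g.standard_normal((n, n_steps)) for g in gens]


def _alloc(n: int):
    return (
        np.zeros(n, dtype=np.bool_),
        np.full(n, np.nan),
        np.zeros(n),
    )


def simulate_go_batch(
    params: ProcessParams,
    cfg: SimConfig,
    n: int,
    seed=None,
    noise: Optional[np.ndarray] = None,
) -> BatchResult:
    """Simulate ``n`` go trials; respond iff theta_e crosses a by the deadline.

    ``noise`` may supply a pre-generated (n, n_steps) standard-normal
    array (common random numbers during fitting); otherwise it is drawn
    from ``seed``.
    """
    n_steps = cfg.n_steps
    if noise is None:
        (noise,) = _noise(seed, n, n_steps)
    i0 = min(int(round(params.tr / cfg.dt)), n_steps)
    gamma = gain_profile(params.xb, cfg.dt, n_steps - i0)
    resp, rt, auc = _alloc(n)
    _kernels.go_kernel(
        noise, i0, n_steps, params.v_e,
        params.sigma * np.sqrt(cfg.dt), cfg.dt, params.a, gamma, resp, rt, auc,
    )
    return BatchResult(resp, rt, auc)


def simulate_stop_batch(
    model_kind: str,
    params: ProcessParams,
    ssd: float,
    cfg: SimConfig,
    n: int,
    seed=None,
    noise=None,
) -> BatchResult:
    """Simulate ``n`` stop trials at stop-signal delay ``ssd`` under one of
    the three models ("dpm", "independent", "interactive")."""
    if ssd < 0:
        raise ValueError("ssd must be >= 0")
    n_steps = cfg.n_steps
    if noise is None:
        z, zb = _noise(seed, n, n_steps, streams=2)
    else:
        z, zb = noise
    i0 = min(int(round(params.tr / cfg.dt)), n_steps)
    gamma = gain_profile(params.xb, cfg.dt, n_steps - i0)
    sdt = params.sigma * np.sqrt(cfg.dt)
    resp, rt, auc = _alloc(n)
    ks = int(round(ssd / cfg.dt))
    if model_kind == "dpm":
        _kernels.dpm_stop_kernel(
            z, zb, i0, ks, n_steps, params.v_e, params.v_b, sdt, cfg.dt,
            params.a, gamma, resp, rt, auc,
        )
    elif model_kind == "independent":
        _kernels.independent_stop_kernel(
            z, zb, i0, ks, n_steps, params.v_e, params.v_b, sdt, cfg.dt,
            params.a, gamma, resp, rt, auc,
        )
    elif model_kind == "interactive":
        if params.sso is None:
            raise ValueError("interactive race model requires an sso parameter")
        kst = int(round((ssd + params.sso) / cfg.dt))
        _kernels.interactive_stop_kernel(
            z, zb, i0, kst, n_steps, params.v_e, params.v_b, sdt, cfg.dt,
            params.a, gamma, resp, rt, auc,
        )
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")
    return BatchResult(resp, rt, auc)


def _single(batch: BatchResult, ssd=None, cue=None) -> TrialOutcome:
    responded = bool(batch.responded[0])
    return TrialOutcome(
        responded=responded,
        rt=float(batch.rt[0]) if responded else None,
        ssd=ssd,
        cue=cue,
    )


def simulate_go_trial(params: ProcessParams, cfg: SimConfig, rng=None, seed=None) -> TrialOutcome:
    """One go trial.  ``rng`` may be a Generator (a fresh integer seed is
    drawn from it) or ``seed`` may be given directly."""
    if seed is None:
        seed = _seed_from(rng)
    return _single(simulate_go_batch(params, cfg, 1, seed=seed))


def simulate_dpm_stop_trial(params, ssd, cfg, rng=None, seed=None) -> TrialOutcome:
    if seed is None:
        seed = _seed_from(rng)
    return _single(simulate_stop_batch("dpm", params, ssd, cfg, 1, seed=seed), ssd=ssd)


def simulate_independent_stop_trial(params, ssd, cfg, rng=None, seed=None) -> TrialOutcome:
    if seed is None:
        seed = _seed_from(rng)
    return _single(simulate_stop_batch("independent", params, ssd, cfg, 1, seed=seed), ssd=ssd)


def simulate_interactive_stop_trial(params, ssd, cfg, rng=None, seed=None) -> TrialOutcome:
    if seed is None:
        seed = _seed_from(rng)
    return _single(simulate_stop_batch("interactive", params, ssd, cfg, 1, seed=seed), ssd=ssd)


def _seed_from(rng) -> int:
    if rng is None:
        raise ValueError("provide either rng or seed")
    return int(rng.integers(0, 2**31 - 1))


def _check_modulation(spec: ModulationSpec, params_by_condition: Mapping[str, ProcessParams]):
    missing = [c for c in spec.conditions if c not in params_by_condition]
    if missing:
        raise ValueError(f"missing parameters for conditions: {missing}")
    fixed = [
        f for f in ("a", "tr", "v_e", "v_b", "xb", "sigma", "sso")
        if f not in spec.free_params
    ]
    ref = params_by_condition[spec.conditions[0]]
    for c in spec.conditions[1:]:
        p = params_by_condition[c]
        for f in fixed:
            if getattr(p, f) != getattr(ref, f):
                raise ValueError(
                    f"parameter {f!r} differs across conditions but is not in "
                    f"the free set {spec.free_params!r}"
                )


def simulate_dataset(
    spec: ModulationSpec,
    design: TaskDesign,
    params_by_condition: Mapping[str, ProcessParams],
    cfg: SimConfig,
    seed: int,
    n_go: Optional[int] = None,
    n_stop_per_ssd: Optional[int] = None,
    n_per_cue: Optional[int] = None,
    subject: str = "s00",
) -> pd.DataFrame:
    """Simulate a full trial table for one subject.

    Reactive designs produce ``n_go`` go trials plus ``n_stop_per_ssd``
    stop trials at every SSD, per condition; proactive designs produce
    ``n_per_cue`` go-process trials at every cue (the single late stop
    signal plays no causal role and is not simulated as a braking event).
    Defaults derive from ``cfg.n_trials`` and the design's stop fraction.
    Output is reproducible under a fixed seed.
    """
    _check_modulation(spec, params_by_condition)
    cfg = cfg.replace(deadline=design.deadline)
    ss = np.random.SeedSequence(seed)
    rows = []
    if design.kind == "reactive":
        n_go = cfg.n_trials if n_go is None else n_go
        if n_stop_per_ssd is None:
            sf = design.stop_fraction
            total_stop = n_go * sf / (1 - sf) if sf < 1 else 0
            n_stop_per_ssd = int(round(total_stop / max(len(design.ssds), 1)))
        cells = []
        for cond in spec.conditions:
            cells.append((cond, "go", None, n_go))
            for ssd in design.ssds:
                cells.append((cond, "stop", ssd, n_stop_per_ssd))
    else:
        if len(spec.conditions) != len(design.cues):
            raise ValueError(
                "proactive simulation requires one condition label per cue"
            )
        n_per_cue = cfg.n_trials if n_per_cue is None else n_per_cue
        cells = [
            (cond, "go", None, n_per_cue)
            for cond in spec.conditions
        ]
    child_seeds = ss.spawn(len(cells))
    for (cond, trial_type, ssd, n), cseed in zip(cells, child_seeds):
        if n == 0:
            continue
        p = params_by_condition[cond]
        if trial_type == "go":
            batch = simulate_go_batch(p, cfg, n, seed=cseed)
        else:
            batch = simulate_stop_batch(spec.model_kind, p, ssd, cfg, n, seed=cseed)
        cue = None
        if design.kind == "proactive":
            cue = design.cues[spec.conditions.index(cond)]
        df = pd.DataFrame(
            {
                "subject": subject,
                "condition": cond,
                "task": design.kind,
                "trial_type": trial_type,
                "ssd": np.nan if ssd is None else ssd,
                "cue": np.nan if cue is None else cue,
                "response": batch.responded.astype(int),
                "rt": batch.rt,
            }
        )
        rows.append(df)
    if not rows:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    return pd.concat(rows, ignore_index=True)[TRIAL_COLUMNS]
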