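"""Synthetic multi-subject cohorts with known ground-truth parameters.

Fixture machinery for weight construction, parameter-recovery and
model-recovery studies: subject-level parameters are drawn around a
known truth with Gaussian between-subject dispersion (truncated to the
plausible parameter boxes), trial tables are simulated per subject, and
the truth record is kept alongside.  There is no claim that real
between-subject variability is Gaussian — this generator exists so that
the full pipeline can be exercised end-to-end without any external data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .fitting import (
    FitConfig,
    FitResult,
    WeightSet,
    accuracy_weights,
    quantile_weights,
    run_fit,
)
from .models import simulate_dataset
from .params import PARAM_BOUNDS, ModulationSpec, ProcessParams, SimConfig, TaskDesign
from .stats import ObservedSummary, summarize

__all__ = ["CohortSpec", "generate_cohort", "recovery_harness", "cohort_weights"]

_PERTURBABLE = ("a", "tr", "v_e", "v_b", "xb", "sso")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort.

    ``between_subject_sd`` maps parameter names to the SD of the
    subject-level Gaussian perturbation (same units as the parameter);
    a subject's offset for a parameter is shared across conditions so
    the modulation structure is preserved.  Draws falling outside the
    plausible parameter boxes are redrawn (and finally clipped).
    """

    n_subjects: int
    design: TaskDesign
    model: ModulationSpec
    params_by_condition: Mapping[str, ProcessParams]
    between_subject_sd: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0
    n_go: Optional[int] = None
    n_stop_per_ssd: Optional[int] = None
    n_per_cue: Optional[int] = None
    dt: float = 0.001

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(sd < 0 for sd in self.between_subject_sd.values()):
            raise ValueError("between-subject dispersions must be >= 0")


def _perturb(
    params: ProcessParams, offsets: Mapping[str, float]
) -> ProcessParams:
    kwargs = {}
    for name, off in offsets.items():
        base = getattr(params, name)
        if base is None:
            continue
        lo, hi = PARAM_BOUNDS.get(name, (-np.inf, np.inf))
        kwargs[name] = float(np.clip(base + off, max(lo, 1e-6), hi))
    return params.replace(**kwargs) if kwargs else params


def _draw_offsets(spec: CohortSpec, rng: np.random.Generator) -> Dict[str, float]:
    """One offset per perturbed parameter, redrawn (up to 100 times) until
    every condition's perturbed value stays inside its box."""
    offsets: Dict[str, float] = {}
    for name, sd in spec.between_subject_sd.items():
        if name not in _PERTURBABLE or sd == 0:
            offsets[name] = 0.0
            continue
        lo, hi = PARAM_BOUNDS.get(name, (-np.inf, np.inf))
        for _ in range(100):
            off = float(rng.normal(0.0, sd))
            ok = all(
                lo < getattr(p, name) + off <= hi
                for p in spec.params_by_condition.values()
                if getattr(p, name) is not None
            )
            if ok:
                break
        offsets[name] = off
    return offsets


def generate_cohort(spec: CohortSpec) -> Tuple[pd.DataFrame, dict]:
    """Simulate every subject's trial table; returns (table, truth record).

    The concatenated table carries per-subject ids s00, s01, ...; the
    truth record stores the group-level parameters, each subject's
    perturbed parameters, and the generating seed.  Byte-identical under
    a fixed seed.
    """
    ss = np.random.SeedSequence(spec.seed)
    param_seeds = ss.spawn(spec.n_subjects)
    data_seeds = ss.spawn(spec.n_subjects)
    tables = []
    truth_subjects = {}
    cfg = SimConfig(dt=spec.dt, deadline=spec.design.deadline, n_trials=100)
    for i in range(spec.n_subjects):
        sid = f"s{i:02d}"
        rng = np.random.default_rng(param_seeds[i])
        offsets = _draw_offsets(spec, rng)
        subj_params = {
            c: _perturb(p, offsets) for c, p in spec.params_by_condition.items()
        }
        table = simulate_dataset(
            spec.model,
            spec.design,
            subj_params,
            cfg,
            seed=int(data_seeds[i].generate_state(1)[0] % (2**31 - 1)),
            n_go=spec.n_go,
            n_stop_per_ssd=spec.n_stop_per_ssd,
            n_per_cue=spec.n_per_cue,
            subject=sid,
        )
        tables.append(table)
        truth_subjects[sid] = {c: p.as_dict() for c, p in subj_params.items()}
    truth = {
        "seed": spec.seed,
        "model_kind": spec.model.model_kind,
        "modulation": spec.model.modulation,
        "conditions": list(spec.model.conditions),
        "params_by_condition": {
            c: p.as_dict() for c, p in spec.params_by_condition.items()
        },
        "subjects": truth_subjects,
    }
    return pd.concat(tables, ignore_index=True), truth


def cohort_weights(table: pd.DataFrame, design: TaskDesign) -> WeightSet:
    """Weights estimated from a cohort table.

    Quantile weights use Maritz-Jarrett SEs of the pooled RT samples;
    response-probability weights use the between-subject SD of each
    condition's probability when at least two subjects are present
    (otherwise they stay at 1)."""
    nq_ones = None
    if design.kind == "reactive":
        go = table[table["trial_type"] == "go"]
        stop = table[table["trial_type"] == "stop"]
        go_rts = go.loc[go["response"] == 1, "rt"].to_numpy()
        err_rts = stop.loc[stop["response"] == 1, "rt"].to_numpy()
        w = WeightSet.unit("reactive", design)
        if go_rts.size >= 10:
            w.w_c = quantile_weights(go_rts)
        if err_rts.size >= 10:
            w.w_e = quantile_weights(err_rts)
        subjects = table["subject"].unique()
        if len(subjects) >= 2:
            mat = []
            for s in subjects:
                st = stop[stop["subject"] == s]
                mat.append(
                    [
                        1.0 - st.loc[np.isclose(st["ssd"], ssd), "response"].mean()
                        for ssd in design.ssds
                    ]
                )
            mat = np.asarray(mat)
            if np.all(np.isfinite(mat)):
                w.w_d = accuracy_weights(mat)
        return w
    else:
        hi = table[table["cue"] > 0.5]
        lo = table[table["cue"] < 0.5]
        hi_rts = hi.loc[hi["response"] == 1, "rt"].to_numpy()
        lo_rts = lo.loc[lo["response"] == 1, "rt"].to_numpy()
        w = WeightSet.unit("proactive", design)
        if hi_rts.size >= 10:
            w.w_h = quantile_weights(hi_rts)
        if lo_rts.size >= 10:
            w.w_l = quantile_weights(lo_rts)
        subjects = table["subject"].unique()
        if len(subjects) >= 2:
            mat = []
            for s in subjects:
                st = table[table["subject"] == s]
                mat.append(
                    [
                        st.loc[np.isclose(st["cue"], cue), "response"].mean()
                        for cue in design.cues
                    ]
                )
            mat = np.asarray(mat)
            if np.all(np.isfinite(mat)):
                w.w_p = accuracy_weights(mat)
        return w


def _summaries_for_fit(spec: ModulationSpec, design: TaskDesign, table: pd.DataFrame):
    if design.kind == "reactive":
        return {
            c: summarize(table[table["condition"] == c], design)
            for c in spec.conditions
        }
    return summarize(table, design)


def recovery_harness(
    spec: CohortSpec,
    model_to_fit: ModulationSpec,
    cfg: FitConfig,
) -> dict:
    """Generate a cohort, fit ``model_to_fit`` to the pooled data, and
    report truth vs estimate per parameter (bias and relative error).

    Fit failures are recorded in the report rather than raised.
    """
    table, truth = generate_cohort(spec)
    weights = cohort_weights(table, spec.design)
    data = _summaries_for_fit(model_to_fit, spec.design, table)
    report: dict = {"truth": truth, "fit_model": model_to_fit.model_kind,
                    "fit_modulation": model_to_fit.modulation}
    try:
        result = run_fit(model_to_fit, data, spec.design, cfg, weights)
    except Exception as exc:  # robustness contract: record, don't crash
        report["error"] = f"{type(exc).__name__}: {exc}"
        return report
    report["fit"] = result.to_dict()
    matched = model_to_fit.model_kind == spec.model.model_kind and set(
        model_to_fit.conditions
    ) == set(spec.model.conditions)
    if matched:
        per_param = {}
        for c in model_to_fit.conditions:
            true_p = spec.params_by_condition[c]
            est_p = result.params_by_condition[c]
            for name in ("a", "tr", "v_e", "v_b", "xb", "sso"):
                t = getattr(true_p, name)
                e = getattr(est_p, name)
                if t is None or e is None:
                    continue
                entry = per_param.setdefault(name, {})
                entry[c] = {
                    "truth": t,
                    "estimate": e,
                    "bias": e - t,
                    "rel_err": abs(e - t) / abs(t) if t != 0 else float("nan"),
                }
        report["recovery"] = per_param
    return report
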