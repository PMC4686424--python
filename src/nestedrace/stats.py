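"""Summary statistics of trial tables: RT quantiles, accuracy curves, PSE.

These summaries are the fitting target: the weighted-quantile cost
compares observed and model-predicted response probabilities and RT
quantiles, so data and simulation are summarised with exactly the same
definitions (linear-interpolation quantiles throughout).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize

from .params import TaskDesign

__all__ = [
    "QUANTILE_PROBS",
    "ObservedSummary",
    "LogisticFit",
    "rt_quantiles",
    "summarize",
    "average_summaries",
    "flatten_proactive",
    "logistic_pse",
]

#: Quantile levels entering the cost function.
QUANTILE_PROBS = (0.1, 0.3, 0.5, 0.7, 0.9)


def rt_quantiles(rts, probs: Sequence[float] = QUANTILE_PROBS) -> np.ndarray:
    """Linear-interpolation (type-7) quantiles of a sample of RTs."""
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("cannot compute quantiles of an empty RT sample")
    return np.quantile(rts, probs)


@dataclass
class ObservedSummary:
    """Response probabilities, RT quantiles and multipliers for one condition.

    Reactive fields: ``p_go`` (response probability on go trials),
    ``p_stop_by_ssd`` (probability of successfully withholding per SSD),
    ``q_correct``/``q_error`` (RT quantiles of go-trial responses and of
    stop-trial responses pooled across SSDs), ``p_corr``/``p_err``
    (response probabilities multiplying the quantile cost terms).

    Proactive fields: ``p_resp_by_cue`` (response probability per cue),
    ``q_hi``/``q_lo`` (RT quantiles pooled over cues above/below 50%),
    ``p_high``/``p_low``.
    """

    kind: str
    p_go: Optional[float] = None
    p_stop_by_ssd: Optional[np.ndarray] = None
    q_correct: Optional[np.ndarray] = None
    q_error: Optional[np.ndarray] = None
    p_corr: Optional[float] = None
    p_err: Optional[float] = None
    p_resp_by_cue: Optional[np.ndarray] = None
    q_hi: Optional[np.ndarray] = None
    q_lo: Optional[np.ndarray] = None
    p_high: Optional[float] = None
    p_low: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("p_stop_by_ssd", "q_correct", "q_error", "p_resp_by_cue", "q_hi", "q_lo"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        for qname in ("q_correct", "q_error", "q_hi", "q_lo"):
            q = getattr(self, qname)
            if q is not None and np.any(np.diff(q) < 0):
                raise ValueError(f"{qname} must be non-decreasing")


def _maybe_quantiles(rts: np.ndarray, min_n: int = 1) -> Optional[np.ndarray]:
    rts = rts[np.isfinite(rts)]
    return rt_quantiles(rts) if rts.size >= min_n else None


def summarize(table: pd.DataFrame, design: TaskDesign) -> ObservedSummary:
    """Summarise a trial table (one condition) into the fitting observables.

    Reactive tables yield the go-response probability, per-SSD stop
    accuracy, correct-RT quantiles and error-RT quantiles collapsed
    across SSDs.  Proactive tables yield per-cue response probabilities
    and RT quantiles pooled over high (>50%) and low (<50%) cues.
    Missing cells leave the corresponding fields as None (and zero
    multipliers for absent response pools).
    """
    if design.kind == "reactive":
        go = table[table["trial_type"] == "go"]
        stop = table[table["trial_type"] == "stop"]
        p_go = float(go["response"].mean()) if len(go) else None
        p_stop = np.array(
            [
                1.0 - s["response"].mean() if len(s) else np.nan
                for ssd in design.ssds
                for s in (stop[np.isclose(stop["ssd"], ssd)],)
            ]
        )
        go_rts = go.loc[go["response"] == 1, "rt"].to_numpy()
        err_rts = stop.loc[stop["response"] == 1, "rt"].to_numpy()
        p_err = float(stop["response"].mean()) if len(stop) else 0.0
        return ObservedSummary(
            kind="reactive",
            p_go=p_go,
            p_stop_by_ssd=p_stop if len(stop) else None,
            q_correct=_maybe_quantiles(go_rts),
            q_error=_maybe_quantiles(err_rts),
            p_corr=p_go,
            p_err=p_err,
        )
    else:
        p_by_cue = []
        for cue in design.cues:
            cell = table[np.isclose(table["cue"], cue)]
            p_by_cue.append(cell["response"].mean() if len(cell) else np.nan)
        hi = table[table["cue"] > 0.5]
        lo = table[table["cue"] < 0.5]
        hi_rts = hi.loc[hi["response"] == 1, "rt"].to_numpy()
        lo_rts = lo.loc[lo["response"] == 1, "rt"].to_numpy()
        return ObservedSummary(
            kind="proactive",
            p_resp_by_cue=np.array(p_by_cue, dtype=float),
            q_hi=_maybe_quantiles(hi_rts),
            q_lo=_maybe_quantiles(lo_rts),
            p_high=float(hi["response"].mean()) if len(hi) else 0.0,
            p_low=float(lo["response"].mean()) if len(lo) else 0.0,
        )


def _mean_of(values):
    vals = [v for v in values if v is not None]
    if not vals:
        return None
    arrs = [np.asarray(v, dtype=float) for v in vals]
    out = np.mean(arrs, axis=0)
    return float(out) if out.ndim == 0 else out


def average_summaries(summaries: Sequence[ObservedSummary]) -> ObservedSummary:
    """Element-wise average of summaries across conditions (the target of
    the flat, all-parameters-free optimization stage)."""
    kinds = {s.kind for s in summaries}
    if len(kinds) != 1:
        raise ValueError("cannot average summaries of mixed task kinds")
    kind = kinds.pop()
    fields = (
        ("p_go", "p_stop_by_ssd", "q_correct", "q_error", "p_corr", "p_err")
        if kind == "reactive"
        else ("p_resp_by_cue", "q_hi", "q_lo", "p_high", "p_low")
    )
    kwargs = {f: _mean_of([getattr(s, f) for s in summaries]) for f in fields}
    return ObservedSummary(kind=kind, **kwargs)


def flatten_proactive(summary: ObservedSummary):
    """Collapse a proactive summary to the flat-stage target: the mean
    response probability across cues and the element-wise mean of the
    high and low pooled quantile vectors (with the mean multiplier)."""
    p_avg = float(np.nanmean(summary.p_resp_by_cue))
    qs = [q for q in (summary.q_hi, summary.q_lo) if q is not None]
    q_avg = np.mean(qs, axis=0) if qs else None
    p_resp = float(np.mean([summary.p_high or 0.0, summary.p_low or 0.0]))
    return p_avg, q_avg, p_resp


def proactive_mean_rt(table: pd.DataFrame, collapse_low: bool = True) -> pd.Series:
    """Mean go RT per cue for reporting (not part of the fitting cost).

    With ``collapse_low`` the sparse 0/20/40% go-probability cues are
    pooled into a single "low" bin, mirroring how mean RTs are usually
    reported for this task (few responses occur at low cues).
    """
    resp = table[table["response"] == 1].copy()
    if collapse_low:
        resp["cue_bin"] = np.where(
            resp["cue"] < 0.5, "low(0-40%)", resp["cue"].map("{:.0%}".format)
        )
    else:
        resp["cue_bin"] = resp["cue"].map("{:.0%}".format)
    return resp.groupby("cue_bin")["rt"].mean()


@dataclass(frozen=True)
class LogisticFit:
    """Logistic psychometric fit on the linear predictor lambda*x + lambda0."""

    slope: float
    intercept: float
    separation_flagged: bool = False

    @property
    def pse(self) -> float:
        """Point of subjective equality, -lambda0 / lambda: the stimulus
        level at which the fitted curve crosses 50%."""
        if self.slope == 0:
            raise ZeroDivisionError("PSE is undefined for a zero slope")
        return -self.intercept / self.slope


def logistic_pse(x, y, n=None) -> LogisticFit:
    """Maximum-likelihood logistic regression of outcome on stimulus level.

    ``y`` may be binary outcomes (one per row of ``x``) or proportions,
    in which case ``n`` gives the binomial count per level.  Perfect
    separation falls back to a lightly ridge-penalised fit and is
    flagged on the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct stimulus levels")
    if np.all(y == y[0]):
        raise ValueError("constant outcomes: PSE undefined")
    if n is None:
        n = np.ones_like(y)
    n = np.asarray(n, dtype=float)
    exog = sm.add_constant(x)
    endog = np.column_stack([y * n, (1 - y) * n])
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
            params = np.asarray(res.params)
            if np.all(np.isfinite(params)) and np.abs(params).max() < 1e3:
                return LogisticFit(slope=float(params[1]), intercept=float(params[0]))
        except Exception:
            pass
    # (near-)separated data: ridge-penalised binomial deviance
    def negll(beta):
        eta = beta[0] + beta[1] * x
        p = 1.0 / (1.0 + np.exp(-eta))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        ll = n * (y * np.log(p) + (1 - y) * np.log(1 - p))
        return -ll.sum() + 1e-3 * (beta**2).sum()

    res = minimize(negll, x0=np.zeros(2), method="BFGS")
    return LogisticFit(
        slope=float(res.x[1]), intercept=float(res.x[0]), separation_flagged=True
    )
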