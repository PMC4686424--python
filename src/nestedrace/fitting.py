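"""Weighted-quantile cost functions and the two-stage fitting protocol.

Models are fit by minimising a chi-square-style cost: the weighted sum of
squared errors between observed and simulated response probabilities and
RT quantiles (0.1, 0.3, 0.5, 0.7, 0.9).  Quantile weights derive from
Maritz-Jarrett standard errors (median SE divided by each quantile's SE);
response-probability weights derive from between-subject dispersion
(mean SD divided by each condition's SD).  Quantile cost terms are scaled
by the observed response probability of the pool they summarise.

Optimization is hierarchical: a global basin-hopping stage over all
parameters against condition-averaged data, a per-condition re-seeding
stage for the free (context-modulated) parameters, and a joint
Nelder-Mead simplex polish.  The whole protocol is run several times
(default three) and the run with the lowest AIC is kept.  Predicted
summaries come from fixed-seed simulation with common random numbers
across cost evaluations, which keeps the cost surface locally smooth for
the simplex stage.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import basinhopping, differential_evolution, minimize
from scipy.stats import beta as beta_dist
from scipy.stats import qmc

from .models import simulate_go_batch, simulate_stop_batch
from .params import (
    PARAM_BOUNDS,
    ModulationSpec,
    ProcessParams,
    SimConfig,
    TaskDesign,
)
from .stats import (
    QUANTILE_PROBS,
    ObservedSummary,
    average_summaries,
    flatten_proactive,
    rt_quantiles,
)

__all__ = [
    "WeightSet",
    "FitConfig",
    "FitResult",
    "maritz_jarrett_se",
    "quantile_weights",
    "accuracy_weights",
    "cost_reactive",
    "cost_proactive",
    "information_criteria",
    "best_of_n",
    "ReactivePredictor",
    "ProactivePredictor",
    "fit_flat",
    "fit_conditional",
    "refine_fit",
    "run_fit",
]

_PARAM_ORDER = ("a", "tr", "v_e", "v_b", "xb", "sso")


# ---------------------------------------------------------------------------
# weights


def maritz_jarrett_se(sample, q: float) -> float:
    """Maritz-Jarrett estimate of the standard error of a sample quantile.

    Beta-kernel weights over the order statistics give smoothed first and
    second moments of the q-th quantile; the SE is the square root of the
    implied variance.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 5:
        raise ValueError("Maritz-Jarrett SE requires at least 5 observations")
    if not (0 < q < 1):
        raise ValueError("quantile level must lie in (0, 1)")
    m = int(np.floor(q * n + 0.5))
    m = min(max(m, 1), n)
    i = np.arange(1, n + 1)
    cdf_hi = beta_dist.cdf(i / n, m, n - m + 1)
    cdf_lo = beta_dist.cdf((i - 1) / n, m, n - m + 1)
    w = cdf_hi - cdf_lo
    c1 = np.sum(w * x)
    c2 = np.sum(w * x * x)
    var = max(c2 - c1 * c1, 0.0)
    return float(np.sqrt(var))


def quantile_weights(
    sample, probs: Sequence[float] = QUANTILE_PROBS, cap: float = 10.0
) -> np.ndarray:
    """Relative-precision weights for the RT quantile cost terms.

    weight_i = median(SE_1..SE_5) / SE_i: quantiles estimated with higher
    variability than typical get weight < 1, more stable ones > 1.  Zero
    SEs (degenerate samples) are capped at ``cap``.
    """
    ses = np.array([maritz_jarrett_se(sample, q) for q in probs])
    med = float(np.median(ses))
    if med == 0.0:
        return np.ones(len(probs))
    w = np.where(ses > 0, med / np.maximum(ses, 1e-300), cap)
    return np.minimum(w, cap)


def accuracy_weights(subject_by_condition, cap: float = 10.0) -> np.ndarray:
    """Relative-precision weights for response-probability cost terms.

    From a (subjects x conditions) matrix of probabilities:
    weight_c = mean(SD_1..SD_C) / SD_c, with zero SDs capped.
    """
    mat = np.asarray(subject_by_condition, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need a (subjects x conditions) matrix with >= 2 subjects")
    sds = mat.std(axis=0, ddof=1)
    mean_sd = sds.mean()
    if mean_sd == 0.0:
        return np.ones(mat.shape[1])
    w = np.where(sds > 0, mean_sd / np.maximum(sds, 1e-300), cap)
    return np.minimum(w, cap)


@dataclass
class WeightSet:
    """Weights entering the reactive (w_g, w_d, w_c, w_e) or proactive
    (w_p, w_h, w_l) cost.  All entries must be positive."""

    kind: str
    w_g: float = 1.0
    w_d: Optional[np.ndarray] = None
    w_c: Optional[np.ndarray] = None
    w_e: Optional[np.ndarray] = None
    w_p: Optional[np.ndarray] = None
    w_h: Optional[np.ndarray] = None
    w_l: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for name in ("w_d", "w_c", "w_e", "w_p", "w_h", "w_l"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if np.any(v <= 0):
                    raise ValueError(f"{name} must be strictly positive")
                setattr(self, name, v)
        if self.w_g <= 0:
            raise ValueError("w_g must be strictly positive")

    @classmethod
    def unit(cls, kind: str, design: TaskDesign) -> "WeightSet":
        nq = len(QUANTILE_PROBS)
        if kind == "reactive":
            return cls(
                kind=kind,
                w_g=1.0,
                w_d=np.ones(len(design.ssds)),
                w_c=np.ones(nq),
                w_e=np.ones(nq),
            )
        return cls(
            kind=kind,
            w_p=np.ones(len(design.cues)),
            w_h=np.ones(nq),
            w_l=np.ones(nq),
        )


# ---------------------------------------------------------------------------
# cost functions


def _cost_one_reactive(obs: ObservedSummary, pred: ObservedSummary, w: WeightSet) -> float:
    c = 0.0
    if obs.p_go is not None:
        c += w.w_g * (obs.p_go - pred.p_go) ** 2
    if obs.p_stop_by_ssd is not None:
        c += float(np.sum(w.w_d * (obs.p_stop_by_ssd - pred.p_stop_by_ssd) ** 2))
    if obs.q_correct is not None:
        c += obs.p_corr * float(np.sum(w.w_c * (obs.q_correct - pred.q_correct) ** 2))
    if obs.q_error is not None and obs.p_err > 0:
        c += obs.p_err * float(np.sum(w.w_e * (obs.q_error - pred.q_error) ** 2))
    return c


def cost_reactive(
    obs_by_cond: Mapping[str, ObservedSummary],
    pred_by_cond: Mapping[str, ObservedSummary],
    w: WeightSet,
) -> float:
    """Reactive weighted-SSE cost, summed over contexts.

    Per context: the go response probability, the five per-SSD stop
    accuracies, and the correct/error RT quantile vectors (the quantile
    terms scaled by the observed response probability of their pool).
    """
    if set(obs_by_cond) != set(pred_by_cond):
        raise ValueError("observed and predicted condition sets differ")
    return float(
        sum(
            _cost_one_reactive(obs_by_cond[c], pred_by_cond[c], w)
            for c in obs_by_cond
        )
    )


def cost_proactive(obs: ObservedSummary, pred: ObservedSummary, w: WeightSet) -> float:
    """Proactive weighted-SSE cost: six per-cue response probabilities plus
    the pooled high-cue and low-cue RT quantile vectors."""
    c = float(np.sum(w.w_p * (obs.p_resp_by_cue - pred.p_resp_by_cue) ** 2))
    if obs.q_hi is not None and obs.p_high > 0:
        c += obs.p_high * float(np.sum(w.w_h * (obs.q_hi - pred.q_hi) ** 2))
    if obs.q_lo is not None and obs.p_low > 0:
        c += obs.p_low * float(np.sum(w.w_l * (obs.q_lo - pred.q_lo) ** 2))
    return c


def information_criteria(cost: float, k: int, n: int) -> Tuple[float, float]:
    """AIC/BIC under the Gaussian-SSE convention.

    AIC = n ln(cost/n) + 2k, BIC = n ln(cost/n) + k ln(n).  A cost of
    exactly zero returns -inf for both (a perfect-fit sentinel).
    Comparisons are only meaningful within this convention.
    """
    if cost < 0:
        raise ValueError("cost must be >= 0")
    if n <= k:
        raise ValueError("need more data points than free parameters")
    if cost == 0:
        return float("-inf"), float("-inf")
    base = n * math.log(cost / n)
    return base + 2 * k, base + k * math.log(n)


# ---------------------------------------------------------------------------
# fit configuration / results


@dataclass(frozen=True)
class FitConfig:
    """Optimizer and simulation settings for the fitting protocol.

    The global stage locates the deepest error basin — by default with a
    seeded differential-evolution search (``de_popsize`` x dim
    individuals, ``de_maxiter`` generations; ``global_stage='sobol'``
    falls back to a quasi-random presearch with ``n_multistart``
    simplex descents) — then runs basin hopping from the incumbent for
    at most ``basin_max_iter`` hops (stopping early after
    ``basin_fail_limit`` consecutive failures to improve), each hop
    locally polished by a short simplex; a longer simplex polish closes
    the stage.  ``n_sim_per_eval`` simulated trials per condition feed
    every cost evaluation (common random numbers across evaluations).
    The full protocol is repeated ``n_restarts`` times (>= 3), and the
    winning run is re-polished jointly with a damped Gauss-Newton
    ladder on the weighted residual vector: at each rung of
    ``refine_ladder`` (simulated trials per evaluation) the Jacobian is
    estimated by central differences under common random numbers and
    ``refine_stage_iters`` capped steps are taken.  Escalating the
    simulation resolution is what resolves the shallow trade-off
    valley of the cost surface, whose slope is far below the
    Monte-Carlo noise of the exploration stage.
    """

    n_sim_per_eval: int = 10_000
    global_stage: str = "de"  # "de" (differential evolution) | "sobol"
    de_popsize: int = 12
    de_maxiter: int = 40
    n_presearch: int = 128
    n_multistart: int = 2
    basin_max_iter: int = 100
    basin_fail_limit: int = 40
    basin_local_maxfev: int = 30
    polish_maxfev: int = 600
    cond_basin_max_iter: int = 20
    cond_basin_fail_limit: int = 10
    n_restarts: int = 3
    joint_refine: bool = True
    refine_ladder: Tuple[int, ...] = (12_000, 50_000, 150_000)
    refine_stage_iters: Tuple[int, ...] = (16, 12, 14)
    #: per-rung finite-difference steps (fractions of each parameter);
    #: shrinking with resolution reduces the secant bias of the
    #: Gauss-Newton stationary point
    refine_fd: Tuple[float, ...] = (0.02, 0.01, 0.006)
    refine_lam: float = 1e-4
    refine_max_step: float = 0.10
    step_fraction: float = 0.1
    temperature: float = 1.0
    improve_tol: float = 1e-6
    dt: float = 0.001
    seed: int = 0
    bounds: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(PARAM_BOUNDS)
    )

    def __post_init__(self) -> None:
        if self.n_restarts < 3:
            raise ValueError("the protocol requires at least three restarts")
        if self.basin_max_iter <= 0 or self.basin_fail_limit <= 0:
            raise ValueError("basin-hopping limits must be positive")
        if not (0 < self.dt <= 0.005):
            raise ValueError("dt must be in (0, 0.005]")

    def replace(self, **kwargs) -> "FitConfig":
        return replace(self, **kwargs)


@dataclass
class FitResult:
    """Fitted parameters per condition together with fit statistics."""

    model_kind: str
    modulation: str
    params_by_condition: Dict[str, ProcessParams]
    cost: float
    k: int
    n: int
    aic: float
    bic: float
    trace: List[dict] = field(default_factory=list)
    seed: Optional[int] = None
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "modulation": self.modulation,
            "params_by_condition": {
                c: p.as_dict() for c, p in self.params_by_condition.items()
            },
            "cost": self.cost,
            "k": self.k,
            "n": self.n,
            "aic": self.aic,
            "bic": self.bic,
            "seed": self.seed,
            "converged": self.converged,
            "trace": self.trace,
        }


def best_of_n(results: Sequence[FitResult]) -> FitResult:
    """The run with the lowest AIC; ties broken by lower cost, then by
    earlier run index."""
    if not results:
        raise ValueError("best_of_n requires at least one result")
    order = sorted(range(len(results)), key=lambda i: (results[i].aic, results[i].cost, i))
    return results[order[0]]


# ---------------------------------------------------------------------------
# simulation-backed predictors (common random numbers)


def _fill_quantiles(rts: np.ndarray, deadline: float) -> np.ndarray:
    """Quantiles of a simulated RT pool; an (almost) empty pool maps to a
    flat vector at the deadline, the worst feasible prediction, so the
    cost stays finite and pushes the optimizer back toward responding."""
    rts = rts[np.isfinite(rts)]
    if rts.size == 0:
        return np.full(len(QUANTILE_PROBS), deadline)
    return rt_quantiles(rts)


class ReactivePredictor:
    """Simulates reactive-task summaries for candidate parameters using a
    frozen noise bank, so repeated evaluations differ only through the
    parameters (common random numbers)."""

    def __init__(
        self,
        model_kind: str,
        design: TaskDesign,
        n_go: int,
        n_stop: int,
        dt: float = 0.001,
        seed: int = 0,
    ) -> None:
        self.model_kind = model_kind
        self.design = design
        self.cfg = SimConfig(dt=dt, deadline=design.deadline, seed=seed)
        n_steps = self.cfg.n_steps
        ss = np.random.SeedSequence(seed)
        g = [np.random.Generator(np.random.Philox(c)) for c in ss.spawn(3)]
        self.z_go = g[0].standard_normal((n_go, n_steps))
        self.z_stop = g[1].standard_normal((n_stop, n_steps))
        self.zb = g[2].standard_normal((n_stop, n_steps))
        self.n_go = n_go
        self.n_stop = n_stop

    def predict(self, params: ProcessParams) -> ObservedSummary:
        go = simulate_go_batch(params, self.cfg, self.n_go, noise=self.z_go)
        p_stop, err_rts, p_err = [], [], []
        for ssd in self.design.ssds:
            b = simulate_stop_batch(
                self.model_kind, params, ssd, self.cfg, self.n_stop,
                noise=(self.z_stop, self.zb),
            )
            p_stop.append(1.0 - b.p_respond)
            p_err.append(b.p_respond)
            err_rts.append(b.rts)
        err_rts = np.concatenate(err_rts) if err_rts else np.empty(0)
        return ObservedSummary(
            kind="reactive",
            p_go=go.p_respond,
            p_stop_by_ssd=np.array(p_stop),
            q_correct=_fill_quantiles(go.rts, self.design.deadline),
            q_error=_fill_quantiles(err_rts, self.design.deadline),
            p_corr=go.p_respond,
            p_err=float(np.mean(p_err)),
        )


class ProactivePredictor:
    """Simulates proactive-task summaries (go process only) per cue with a
    shared frozen noise bank."""

    def __init__(
        self, design: TaskDesign, n_per_cue: int, dt: float = 0.001, seed: int = 0
    ) -> None:
        self.design = design
        self.cfg = SimConfig(dt=dt, deadline=design.deadline, seed=seed)
        ss = np.random.SeedSequence(seed)
        g = np.random.Generator(np.random.Philox(ss.spawn(1)[0]))
        self.z = g.standard_normal((n_per_cue, self.cfg.n_steps))
        self.n_per_cue = n_per_cue

    def predict(self, params_by_cue: Sequence[ProcessParams]) -> ObservedSummary:
        if len(params_by_cue) != len(self.design.cues):
            raise ValueError("need one parameter set per cue")
        p_by_cue, hi_rts, lo_rts, hi_resp, lo_resp = [], [], [], [], []
        for cue, p in zip(self.design.cues, params_by_cue):
            b = simulate_go_batch(p, self.cfg, self.n_per_cue, noise=self.z)
            p_by_cue.append(b.p_respond)
            if cue > 0.5:
                hi_rts.append(b.rts)
                hi_resp.append(b.p_respond)
            elif cue < 0.5:
                lo_rts.append(b.rts)
                lo_resp.append(b.p_respond)
        hi = np.concatenate(hi_rts) if hi_rts else np.empty(0)
        lo = np.concatenate(lo_rts) if lo_rts else np.empty(0)
        return ObservedSummary(
            kind="proactive",
            p_resp_by_cue=np.array(p_by_cue),
            q_hi=_fill_quantiles(hi, self.design.deadline),
            q_lo=_fill_quantiles(lo, self.design.deadline),
            p_high=float(np.mean(hi_resp)) if hi_resp else 0.0,
            p_low=float(np.mean(lo_resp)) if lo_resp else 0.0,
        )

    def predict_single_cue(self, params: ProcessParams) -> float:
        """Response probability for one cue only (cheap per-condition stage)."""
        return simulate_go_batch(params, self.cfg, self.n_per_cue, noise=self.z).p_respond

    def predict_flat(self, params: ProcessParams):
        b = simulate_go_batch(params, self.cfg, self.n_per_cue, noise=self.z)
        return b.p_respond, _fill_quantiles(b.rts, self.design.deadline), b.p_respond


# ---------------------------------------------------------------------------
# optimization machinery


def _param_names(spec: ModulationSpec, design: TaskDesign) -> Tuple[str, ...]:
    names = ["a", "tr", "v_e", "xb"]
    if design.kind == "reactive":
        names.insert(3, "v_b")
        if spec.model_kind == "interactive":
            names.append("sso")
    return tuple(n for n in _PARAM_ORDER if n in names)


def _make_params(values: Mapping[str, float], sigma: float = 0.1) -> ProcessParams:
    return ProcessParams(
        a=values["a"],
        tr=values["tr"],
        v_e=values["v_e"],
        v_b=values.get("v_b", 0.0),
        xb=values.get("xb", 0.0),
        sigma=sigma,
        sso=values.get("sso"),
    )


class _BoxStep:
    """Uniform random displacement of 2*step_fraction of each box width,
    clipped to the box."""

    def __init__(self, lo, hi, step_fraction, rng):
        self.lo, self.hi = lo, hi
        self.scale = step_fraction * (hi - lo)
        self.rng = rng

    def __call__(self, x):
        x = x + self.rng.uniform(-1, 1, size=len(x)) * self.scale
        return np.clip(x, self.lo, self.hi)


def _boxed(fun, lo, hi):
    def wrapped(x):
        below = np.maximum(lo - x, 0.0)
        above = np.maximum(x - hi, 0.0)
        viol = below.sum() + above.sum()
        if viol > 0:
            return 1e6 * (1.0 + viol)
        return fun(x)

    return wrapped


def _damped_gauss_newton(
    resid,
    x0,
    lo,
    hi,
    n_iter: int,
    fd: float = 0.02,
    lam: float = 1e-4,
    max_step: float = 0.10,
    avg_tail: int = 0,
):
    """Damped Gauss-Newton steps on a weighted residual vector.

    The Jacobian is estimated by central finite differences at a few
    percent of each parameter's magnitude; under common random numbers
    the simulation noise largely cancels in the differences, so the
    Jacobian tracks the smooth expected residuals even where the cost
    itself is too jagged for line searches.  Steps are always taken
    (no acceptance test against the corrugated cost) but are damped and
    capped at ``max_step`` of each parameter's magnitude.  Along the
    shallowest direction the iterates random-walk around the expected
    minimum, so with ``avg_tail`` > 0 the mean of the last iterates is
    returned (Polyak-style averaging).  Returns (x, nfev).
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    x = np.clip(np.asarray(x0, dtype=float), lo, hi)
    nfev = 0
    tail = []
    for _ in range(n_iter):
        r0 = resid(x)
        nfev += 1
        h = np.maximum(fd * np.abs(x), 5e-4)
        J = np.empty((len(r0), len(x)))
        for j in range(len(x)):
            xp = x.copy()
            xp[j] = min(x[j] + h[j], hi[j])
            xm = x.copy()
            xm[j] = max(x[j] - h[j], lo[j])
            J[:, j] = (resid(xp) - resid(xm)) / (xp[j] - xm[j])
            nfev += 2
        A = J.T @ J
        D = np.diag(np.maximum(np.diag(A), 1e-10))
        try:
            delta = np.linalg.solve(A + lam * D, -J.T @ r0)
        except np.linalg.LinAlgError:
            break
        cap = max_step * np.maximum(np.abs(x), 0.05)
        delta = np.clip(delta, -cap, cap)
        x = np.clip(x + delta, lo, hi)
        tail.append(x.copy())
    if avg_tail > 0 and tail:
        x = np.mean(tail[-avg_tail:], axis=0)
    return x, nfev


def _residuals_reactive(obs_by_cond, pred_by_cond, w: WeightSet) -> np.ndarray:
    """Square-root-weighted residual vector whose squared norm is
    cost_reactive(obs, pred, w)."""
    out = []
    for c in obs_by_cond:
        o, p = obs_by_cond[c], pred_by_cond[c]
        if o.p_go is not None:
            out.append([np.sqrt(w.w_g) * (o.p_go - p.p_go)])
        if o.p_stop_by_ssd is not None:
            out.append(np.sqrt(w.w_d) * (o.p_stop_by_ssd - p.p_stop_by_ssd))
        if o.q_correct is not None:
            out.append(np.sqrt(o.p_corr * w.w_c) * (o.q_correct - p.q_correct))
        if o.q_error is not None and o.p_err > 0:
            out.append(np.sqrt(o.p_err * w.w_e) * (o.q_error - p.q_error))
    return np.concatenate(out)


def _residuals_proactive(obs, pred, w: WeightSet) -> np.ndarray:
    out = [np.sqrt(w.w_p) * (obs.p_resp_by_cue - pred.p_resp_by_cue)]
    if obs.q_hi is not None and obs.p_high > 0:
        out.append(np.sqrt(obs.p_high * w.w_h) * (obs.q_hi - pred.q_hi))
    if obs.q_lo is not None and obs.p_low > 0:
        out.append(np.sqrt(obs.p_low * w.w_l) * (obs.q_lo - pred.q_lo))
    return np.concatenate(out)


def _nm(fun, x0, maxfev):
    return minimize(
        fun,
        np.asarray(x0, dtype=float),
        method="Nelder-Mead",
        options=dict(maxfev=maxfev, xatol=1e-5, fatol=1e-10, adaptive=True),
    )


def _presearch_starts(fun, lo, hi, cfg: FitConfig, seed, extra=()):
    """Quasi-random scan of the box; returns the best n_multistart points."""
    m = max(3, int(np.ceil(np.log2(max(cfg.n_presearch, 8)))))
    sob = qmc.Sobol(len(lo), seed=seed).random_base2(m)
    pts = list(lo + sob * (hi - lo)) + [np.asarray(x) for x in extra]
    costs = [fun(x) for x in pts]
    order = np.argsort(costs)
    return [pts[i] for i in order[: max(1, cfg.n_multistart)]], float(costs[order[0]])


def _two_stage_minimize(
    fun, x0, lo, hi, cfg: FitConfig, rng, niter, niter_success, presearch=True
):
    """Global stage (deep-basin search + basin hopping) followed by a
    Nelder-Mead polish.

    The cost surface has long, shallow valleys where parameters trade
    off, plus genuinely distinct local valleys; hill-descent from a
    single start is unreliable, so each run first locates the deepest
    basin (differential evolution by default) before basin hopping
    around the incumbent.
    """
    f = _boxed(fun, lo, hi)
    nfev = 0
    best_x, best_f = np.asarray(x0, dtype=float), np.inf
    if presearch and cfg.global_stage == "de":
        de = differential_evolution(
            f,
            bounds=list(zip(lo, hi)),
            seed=rng,
            maxiter=cfg.de_maxiter,
            popsize=cfg.de_popsize,
            tol=1e-8,
            mutation=(0.5, 1.0),
            recombination=0.7,
            init="sobol",
            updating="immediate",
            polish=False,
        )
        nfev += int(de.nfev)
        best_x, best_f = de.x, float(de.fun)
    elif presearch:
        seed = int(rng.integers(0, 2**31 - 1))
        starts, _ = _presearch_starts(f, lo, hi, cfg, seed, extra=[x0])
        nfev += cfg.n_presearch
        for s in starts:
            r = _nm(f, s, cfg.polish_maxfev)
            nfev += r.nfev
            if r.fun < best_f:
                best_x, best_f = r.x, float(r.fun)
    mk = dict(
        method="Nelder-Mead",
        options=dict(maxfev=cfg.basin_local_maxfev, xatol=1e-3, fatol=1e-5),
    )
    bh = basinhopping(
        f,
        best_x,
        niter=niter,
        T=cfg.temperature,
        minimizer_kwargs=mk,
        take_step=_BoxStep(lo, hi, cfg.step_fraction, rng),
        niter_success=niter_success,
        rng=rng,
    )
    nfev += bh.nfev
    if bh.fun < best_f:
        best_x, best_f = bh.x, float(bh.fun)
    polish = _nm(f, best_x, cfg.polish_maxfev)
    nfev += polish.nfev
    if polish.fun < best_f:
        best_x, best_f = polish.x, float(polish.fun)
    trace = {"nfev": int(nfev), "basin_fun": float(bh.fun), "fun": best_f}
    return np.clip(best_x, lo, hi), best_f, trace


def _bounds_arrays(names, cfg):
    lo = np.array([cfg.bounds[n][0] for n in names])
    hi = np.array([cfg.bounds[n][1] for n in names])
    return lo, hi


def _data_summaries(spec, data):
    """Normalise the data argument: reactive fits take a mapping
    condition -> ObservedSummary, proactive fits a single summary."""
    if isinstance(data, ObservedSummary):
        return None, data
    return dict(data), None


# ---------------------------------------------------------------------------
# fitting protocol


def fit_flat(
    spec: ModulationSpec,
    data,
    design: TaskDesign,
    cfg: FitConfig,
    weights: Optional[WeightSet] = None,
    seed: Optional[int] = None,
    x0: Optional[Mapping[str, float]] = None,
):
    """Global stage: all parameters free against condition-averaged data.

    Returns (ProcessParams, trace dict).  The averaged target is the
    element-wise mean of the per-condition summaries (reactive) or the
    collapsed single-probability / averaged-quantile target (proactive).
    """
    seed = cfg.seed if seed is None else seed
    obs_by_cond, obs_single = _data_summaries(spec, data)
    weights = weights or WeightSet.unit(design.kind, design)
    names = _param_names(spec, design)
    lo, hi = _bounds_arrays(names, cfg)
    rng = np.random.default_rng(seed)

    if design.kind == "reactive":
        obs_avg = (
            average_summaries(list(obs_by_cond.values()))
            if obs_by_cond is not None
            else obs_single
        )
        pred = ReactivePredictor(
            spec.model_kind, design, cfg.n_sim_per_eval, cfg.n_sim_per_eval,
            dt=cfg.dt, seed=seed,
        )

        def fun(x):
            p = _make_params(dict(zip(names, x)))
            return _cost_one_reactive(obs_avg, pred.predict(p), weights)

    else:
        obs = obs_single if obs_single is not None else average_summaries(
            list(obs_by_cond.values())
        )
        p_avg, q_avg, p_resp_obs = flatten_proactive(obs)
        pred = ProactivePredictor(design, cfg.n_sim_per_eval, dt=cfg.dt, seed=seed)
        w_p = float(np.mean(weights.w_p))
        w_q = np.mean([weights.w_h, weights.w_l], axis=0)

        def fun(x):
            p = _make_params(dict(zip(names, x)))
            ph, qh, _ = pred.predict_flat(p)
            c = w_p * (p_avg - ph) ** 2
            if q_avg is not None:
                c += p_resp_obs * float(np.sum(w_q * (q_avg - qh) ** 2))
            return c

    if x0 is None:
        x0_arr = (lo + hi) / 2.0
    else:
        x0_arr = np.array([x0[n] for n in names])
    x, val, trace = _two_stage_minimize(
        fun, x0_arr, lo, hi, cfg, rng, cfg.basin_max_iter, cfg.basin_fail_limit
    )
    trace["stage"] = "flat"
    return _make_params(dict(zip(names, x))), trace


def fit_conditional(
    spec: ModulationSpec,
    data,
    flat_params: ProcessParams,
    design: TaskDesign,
    cfg: FitConfig,
    weights: Optional[WeightSet] = None,
    seed: Optional[int] = None,
) -> FitResult:
    """Conditional stage: per-condition free parameters, shared constants.

    Each free parameter is first re-seeded condition-by-condition with a
    short basin-hopping run (all other parameters held at the flat-stage
    values), then all condition-wise free parameters are polished jointly
    with a Nelder-Mead simplex on the full cost.  With an empty free set
    the flat parameters are returned unchanged (with their fit statistics).
    """
    seed = cfg.seed if seed is None else seed
    obs_by_cond, obs_single = _data_summaries(spec, data)
    weights = weights or WeightSet.unit(design.kind, design)
    names = _param_names(spec, design)
    free = tuple(n for n in _PARAM_ORDER if n in spec.free_params)
    conditions = list(spec.conditions)
    rng = np.random.default_rng(seed)
    flat_vals = {n: getattr(flat_params, n) for n in names}

    if design.kind == "reactive":
        pred = ReactivePredictor(
            spec.model_kind, design, cfg.n_sim_per_eval, cfg.n_sim_per_eval,
            dt=cfg.dt, seed=seed,
        )
        n_points = len(conditions) * (1 + len(design.ssds) + 2 * len(QUANTILE_PROBS))
    else:
        pred = ProactivePredictor(design, cfg.n_sim_per_eval, dt=cfg.dt, seed=seed)
        n_points = len(design.cues) + 2 * len(QUANTILE_PROBS)
        if obs_single is None:
            raise ValueError("proactive fits take a single combined ObservedSummary")

    def full_cost(cond_values: Mapping[str, Mapping[str, float]]) -> float:
        params = {
            c: _make_params({**flat_vals, **cond_values[c]}) for c in conditions
        }
        if design.kind == "reactive":
            preds = {c: pred.predict(params[c]) for c in conditions}
            return cost_reactive(obs_by_cond, preds, weights)
        return cost_proactive(
            obs_single, pred.predict([params[c] for c in conditions]), weights
        )

    trace: List[dict] = []
    if not free:
        cond_values = {c: {} for c in conditions}
        cost = full_cost(cond_values)
        k = len(names)
        aic, bic = information_criteria(cost, k, n_points)
        return FitResult(
            model_kind=spec.model_kind,
            modulation=spec.modulation,
            params_by_condition={c: _make_params(flat_vals) for c in conditions},
            cost=cost, k=k, n=n_points, aic=aic, bic=bic, trace=trace, seed=seed,
        )

    lo_f, hi_f = _bounds_arrays(free, cfg)

    # stage A: re-seed the free parameter(s) individually per condition
    cond_values: Dict[str, Dict[str, float]] = {
        c: {n: flat_vals[n] for n in free} for c in conditions
    }
    for ci, cond in enumerate(conditions):
        if design.kind == "reactive":

            def fun_c(x, cond=cond):
                p = _make_params({**flat_vals, **dict(zip(free, x))})
                return _cost_one_reactive(obs_by_cond[cond], pred.predict(p), weights)

        else:
            cue_p_obs = float(obs_single.p_resp_by_cue[ci])
            w_cue = float(weights.w_p[ci])

            def fun_c(x, cue_p_obs=cue_p_obs, w_cue=w_cue):
                p = _make_params({**flat_vals, **dict(zip(free, x))})
                return w_cue * (cue_p_obs - pred.predict_single_cue(p)) ** 2

        x0 = np.array([flat_vals[n] for n in free])
        x, val, tr = _two_stage_minimize(
            fun_c, x0, lo_f, hi_f, cfg, rng,
            cfg.cond_basin_max_iter, cfg.cond_basin_fail_limit, presearch=False,
        )
        cond_values[cond] = dict(zip(free, x))
        tr["stage"] = f"conditional:{cond}"
        trace.append(tr)

    # stage B: joint simplex over all condition-wise free parameters
    def pack(cv):
        return np.concatenate([[cv[c][n] for n in free] for c in conditions])

    def unpack(x):
        out = {}
        for i, c in enumerate(conditions):
            out[c] = dict(zip(free, x[i * len(free) : (i + 1) * len(free)]))
        return out

    lo_j = np.tile(lo_f, len(conditions))
    hi_j = np.tile(hi_f, len(conditions))
    f_joint = _boxed(lambda x: full_cost(unpack(x)), lo_j, hi_j)
    res = minimize(
        f_joint,
        pack(cond_values),
        method="Nelder-Mead",
        options=dict(
            maxfev=cfg.polish_maxfev * max(1, len(conditions)),
            xatol=1e-4, fatol=1e-8, adaptive=True,
        ),
    )
    x_best = np.clip(res.x, lo_j, hi_j)
    cond_values = unpack(x_best)
    cost = full_cost(cond_values)
    trace.append({"stage": "joint", "nfev": int(res.nfev), "fun": float(res.fun)})

    k = (len(names) - len(free)) + len(free) * len(conditions)
    aic, bic = information_criteria(cost, k, n_points)
    return FitResult(
        model_kind=spec.model_kind,
        modulation=spec.modulation,
        params_by_condition={
            c: _make_params({**flat_vals, **cond_values[c]}) for c in conditions
        },
        cost=cost, k=k, n=n_points, aic=aic, bic=bic, trace=trace, seed=seed,
        converged=bool(res.success or res.fun < np.inf),
    )


def refine_fit(
    spec: ModulationSpec,
    data,
    result: FitResult,
    design: TaskDesign,
    cfg: FitConfig,
    weights: Optional[WeightSet] = None,
    seed: Optional[int] = None,
) -> FitResult:
    """High-resolution joint re-polish of a fit.

    A Nelder-Mead simplex over every fitted parameter (shared constants
    plus all condition-wise free parameters) against the full cost, with
    ``n_sim_refine`` simulated trials per condition.  Near the optimum
    the cost differences between parameter trade-offs are of the order
    of the Monte-Carlo noise at the exploration resolution, so the final
    localisation is done with a larger simulation budget.
    """
    seed = cfg.seed if seed is None else seed
    obs_by_cond, obs_single = _data_summaries(spec, data)
    weights = weights or WeightSet.unit(design.kind, design)
    names = _param_names(spec, design)
    free = tuple(n for n in _PARAM_ORDER if n in spec.free_params)
    constants = tuple(n for n in names if n not in free)
    conditions = list(spec.conditions)

    def _predictor(n_sim, pseed):
        if design.kind == "reactive":
            return ReactivePredictor(
                spec.model_kind, design, n_sim, n_sim, dt=cfg.dt, seed=pseed
            )
        return ProactivePredictor(design, n_sim, dt=cfg.dt, seed=pseed)

    ref = result.params_by_condition[conditions[0]]
    x0 = np.array(
        [getattr(ref, n) for n in constants]
        + [
            getattr(result.params_by_condition[c], n)
            for c in conditions
            for n in free
        ]
    )
    lo_c, hi_c = _bounds_arrays(constants, cfg) if constants else (np.empty(0), np.empty(0))
    lo_f, hi_f = _bounds_arrays(free, cfg) if free else (np.empty(0), np.empty(0))
    lo = np.concatenate([lo_c, np.tile(lo_f, len(conditions))])
    hi = np.concatenate([hi_c, np.tile(hi_f, len(conditions))])

    def unpack(x):
        flat_vals = dict(zip(constants, x[: len(constants)]))
        params = {}
        for i, c in enumerate(conditions):
            off = len(constants) + i * len(free)
            params[c] = _make_params(
                {**flat_vals, **dict(zip(free, x[off : off + len(free)]))}
            )
        return params

    def make_fun(pred):
        def fun(x):
            params = unpack(x)
            if design.kind == "reactive":
                preds = {c: pred.predict(params[c]) for c in conditions}
                return cost_reactive(obs_by_cond, preds, weights)
            return cost_proactive(
                obs_single, pred.predict([params[c] for c in conditions]), weights
            )

        return fun

    def make_resid(pred):
        def resid(x):
            params = unpack(x)
            if design.kind == "reactive":
                preds = {c: pred.predict(params[c]) for c in conditions}
                return _residuals_reactive(obs_by_cond, preds, weights)
            return _residuals_proactive(
                obs_single, pred.predict([params[c] for c in conditions]), weights
            )

        return resid

    # Damped Gauss-Newton ladder: the valley of near-equivalent
    # parameter trade-offs has a slope far below the Monte-Carlo noise
    # of coarse simulation, so each rung raises the simulation
    # resolution and takes capped Gauss-Newton steps whose Jacobian
    # (a common-random-number central difference) sees the smooth
    # expected residuals.
    x = np.asarray(x0, dtype=float)
    nfev = 0
    pred = None
    n_stages = len(cfg.refine_ladder)
    for stage, (n_sim, n_it) in enumerate(
        zip(cfg.refine_ladder, cfg.refine_stage_iters)
    ):
        del pred
        pred = _predictor(n_sim, seed + stage)
        last = stage == n_stages - 1
        fd = (
            cfg.refine_fd[min(stage, len(cfg.refine_fd) - 1)]
            if isinstance(cfg.refine_fd, (tuple, list))
            else cfg.refine_fd
        )
        x, ne = _damped_gauss_newton(
            make_resid(pred), x, lo, hi, n_iter=n_it,
            fd=fd, lam=cfg.refine_lam,
            max_step=cfg.refine_max_step * (0.7 ** stage),
            avg_tail=n_it // 2 if last else 0,
        )
        nfev += ne
    fun_hi = make_fun(pred)
    x_best = np.clip(x, lo, hi)
    cost = fun_hi(x_best)
    aic, bic = information_criteria(cost, result.k, result.n)
    trace = list(result.trace) + [
        {"stage": "refine", "nfev": int(nfev), "fun": float(cost)}
    ]
    return FitResult(
        model_kind=result.model_kind,
        modulation=result.modulation,
        params_by_condition=unpack(x_best),
        cost=cost, k=result.k, n=result.n, aic=aic, bic=bic,
        trace=trace, seed=result.seed, converged=result.converged,
    )


def run_fit(
    spec: ModulationSpec,
    data,
    design: TaskDesign,
    cfg: FitConfig,
    weights: Optional[WeightSet] = None,
) -> FitResult:
    """Full protocol: (flat stage -> conditional stage) x n_restarts, keep
    the restart with the lowest AIC, then re-polish it jointly at the
    refinement resolution."""
    ss = np.random.SeedSequence(cfg.seed)
    restart_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(cfg.n_restarts + 1)]
    results = []
    for rseed in restart_seeds[:-1]:
        flat, flat_trace = fit_flat(spec, data, design, cfg, weights, seed=rseed)
        res = fit_conditional(spec, data, flat, design, cfg, weights, seed=rseed)
        res.trace.insert(0, flat_trace)
        results.append(res)
    best = best_of_n(results)
    if cfg.joint_refine:
        best = refine_fit(
            spec, data, best, design, cfg, weights, seed=restart_seeds[-1]
        )
    return best
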