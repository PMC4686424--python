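"""Single-trial stochastic integration of the gain-modulated execution process.

The execution process is an accumulate-to-bound diffusion with a linear
core, d(phi_e) = v_e dt + sigma dW, started at 0 after an onset delay tr
and scaled multiplicatively by a time-growing urgency signal

    theta_e(t) = phi_e(t) * gamma(t - tr),    gamma(u) = cosh(xb * u).

gamma equals 1 at onset and accelerates the process toward the response
deadline, mimicking a collapsing decision bound.  A response is recorded
if theta_e reaches the boundary a before the trial window expires.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import ProcessParams, SimConfig

__all__ = ["dynamic_gain", "gain_profile", "Trajectory", "integrate_execution", "first_passage"]


def dynamic_gain(t, xb: float):
    """Urgency multiplier gamma(t) = cosh(xb * t) at time(s) ``t`` since onset.

    gamma(0) = 1, gamma is non-decreasing for xb > 0, and gamma == 1
    everywhere when xb = 0 (the bias is disabled).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since onset must be >= 0")
    if xb < 0:
        raise ValueError("gain coefficient xb must be >= 0")
    out = np.cosh(xb * t)
    return float(out) if out.ndim == 0 else out


def gain_profile(xb: float, dt: float, n: int) -> np.ndarray:
    """Gain evaluated after each of ``n`` integration steps since onset.

    Element j multiplies the accumulator state after step j+1, i.e. at
    time (j+1)*dt after onset; matches the kernel discretization.
    """
    return np.cosh(xb * dt * np.arange(1, n + 1))


@dataclass
class Trajectory:
    """A simulated path on the integration grid.

    ``times`` runs from 0 to the termination time (boundary crossing or
    deadline); ``theta_e`` is 0 before the onset delay.  ``theta_b`` is
    present only for stop trials of models with an explicit braking path.
    """

    times: np.ndarray
    theta_e: np.ndarray
    theta_b: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.theta_e):
            raise ValueError("times and theta_e must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0


def integrate_execution(
    params: ProcessParams, cfg: SimConfig, rng: np.random.Generator
) -> Trajectory:
    """Euler-Maruyama path of the execution process for one trial.

    The path starts at 0, accumulates from ``tr`` onward, and terminates
    at the first grid point where theta_e >= a or at the deadline,
    whichever comes first.
    """
    if cfg.dt <= 0:
        raise ValueError("dt must be positive")
    dt = cfg.dt
    n_steps = cfg.n_steps
    i0 = int(round(params.tr / dt))
    times = np.arange(n_steps + 1) * dt
    theta = np.zeros(n_steps + 1)
    if i0 < n_steps:
        m = n_steps - i0
        incr = params.v_e * dt + params.sigma * np.sqrt(dt) * rng.standard_normal(m)
        phi = np.cumsum(incr)
        theta[i0 + 1 :] = phi * gain_profile(params.xb, dt, m)
    crossed = np.nonzero(theta >= params.a)[0]
    end = int(crossed[0]) if crossed.size else n_steps
    return Trajectory(times=times[: end + 1], theta_e=theta[: end + 1])


def first_passage(
    trajectory: Trajectory, boundary: float, direction: str = "up"
) -> Optional[float]:
    """Earliest grid time at which a path weakly crosses ``boundary``.

    ``direction`` is "up" (value >= boundary) or "down" (value <= boundary).
    Returns None if the path never crosses.
    """
    if len(trajectory.times) == 0:
        raise ValueError("trajectory is empty")
    values = trajectory.theta_e
    if direction == "up":
        hits = np.nonzero(values >= boundary)[0]
    elif direction == "down":
        hits = np.nonzero(values <= boundary)[0]
    else:
        raise ValueError("direction must be 'up' or 'down'")
    return float(trajectory.times[hits[0]]) if hits.size else None
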