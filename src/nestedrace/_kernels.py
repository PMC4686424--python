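"""Compiled Euler-Maruyama trial kernels.

All kernels share one discretization: step k integrates the interval
[k*dt, (k+1)*dt], so the state after step k is the state at time
(k+1)*dt.  The execution accumulator starts at 0 and integrates from
step ``i0 = round(tr/dt)`` onward; a boundary crossing at step k yields
rt = (k+1)*dt (measured from trial onset).  Crossings are detected on
the grid without sub-step interpolation, and a crossing is evaluated
before the deadline within the same step (response wins the tie).

Noise arrays are indexed by the absolute step k so that a trial's noise
stream is independent of the parameters being evaluated — this is what
makes common-random-number cost surfaces smooth in tr and ssd.

``gamma`` is the urgency profile indexed by steps since onset:
gamma[j] = cosh(xb * (j+1) * dt) multiplies the accumulator state after
its (j+1)-th step.
"""
import numpy as np
from numba import njit

__all__ = [
    "go_kernel",
    "dpm_stop_kernel",
    "independent_stop_kernel",
    "interactive_stop_kernel",
]


@njit(cache=True)
def go_kernel(z, i0, n_steps, ve, sdt, dt, a, gamma, resp, rt, auc):
    """Execution process only: respond iff theta_e >= a before the deadline."""
    n = z.shape[0]
    for i in range(n):
        phi = 0.0
        s = 0.0
        responded = False
        t = np.nan
        for k in range(i0, n_steps):
            phi += ve * dt + sdt * z[i, k]
            th = phi * gamma[k - i0]
            s += th * dt
            if th >= a:
                responded = True
                t = (k + 1) * dt
                break
        resp[i] = responded
        rt[i] = t
        auc[i] = s


@njit(cache=True)
def dpm_stop_kernel(z, zb, i0, ks, n_steps, ve, vb, sdt, dt, a, gamma, resp, rt, auc):
    """Dependent process model stop trial.

    The braking accumulator is initialised at the execution state at the
    stop-signal delay (step index ks) and drifts at -vb (no urgency gain)
    toward 0; reaching 0 cancels the trial.  A response that occurred
    before the stop signal stands.
    """
    n = z.shape[0]
    start = i0 if i0 < ks else ks
    for i in range(n):
        phi = 0.0
        th = 0.0
        b = 0.0
        s = 0.0
        brake_on = False
        responded = False
        t = np.nan
        for k in range(start, n_steps):
            if k == ks:
                b = th  # execution state at t = ssd
                brake_on = True
                if b <= 0.0:
                    break  # braking starts at (or below) its boundary
            if k >= i0:
                phi += ve * dt + sdt * z[i, k]
                th = phi * gamma[k - i0]
                s += th * dt
                if th >= a:
                    responded = True
                    t = (k + 1) * dt
                    break
            if brake_on:
                b += -vb * dt + sdt * zb[i, k]
                if b <= 0.0:
                    break  # successful stop
        resp[i] = responded
        rt[i] = t
        auc[i] = s


@njit(cache=True)
def independent_stop_kernel(z, zb, i0, ks, n_steps, ve, vb, sdt, dt, a, gamma, resp, rt, auc):
    """Independent race stop trial.

    The braking accumulator starts at 0 at the stop-signal delay and
    races (drift +vb, no gain) to the same boundary a; if it arrives
    before the execution process the trial is cancelled.  The two
    accumulators share no state.
    """
    n = z.shape[0]
    start = i0 if i0 < ks else ks
    for i in range(n):
        phi = 0.0
        b = 0.0
        s = 0.0
        responded = False
        t = np.nan
        for k in range(start, n_steps):
            if k >= i0:
                phi += ve * dt + sdt * z[i, k]
                th = phi * gamma[k - i0]
                s += th * dt
                if th >= a:
                    responded = True
                    t = (k + 1) * dt
                    break
            if k >= ks:
                b += vb * dt + sdt * zb[i, k]
                if b >= a:
                    break  # braking wins the race
        resp[i] = responded
        rt[i] = t
        auc[i] = s


@njit(cache=True)
def interactive_stop_kernel(z, zb, i0, kst, n_steps, ve, vb, sdt, dt, a, gamma, resp, rt, auc):
    """Interactive race stop trial.

    From step ``kst`` (stop-signal delay plus registration delay sso)
    onward, an accumulating braking signal (drift +vb with its own
    diffusion noise) is subtracted from the gain-scaled execution signal;
    a response requires the net signal to reach a before the deadline.
    Responses made before the braking onset stand.
    """
    n = z.shape[0]
    start = i0 if i0 < kst else kst
    for i in range(n):
        phi = 0.0
        th = 0.0
        brake = 0.0
        s = 0.0
        responded = False
        t = np.nan
        for k in range(start, n_steps):
            if k >= i0:
                phi += ve * dt + sdt * z[i, k]
                th = phi * gamma[k - i0]
            if k >= kst:
                brake += vb * dt + sdt * zb[i, k]
            net = th - brake
            s += net * dt
            if net >= a:
                responded = True
                t = (k + 1) * dt
                break
        resp[i] = responded
        rt[i] = t
        auc[i] = s
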