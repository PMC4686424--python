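"""Core parameter and configuration containers.

All times are in seconds, evidence in arbitrary "evidence units", drift
rates in evidence/s, and the diffusion constant sigma in evidence/sqrt(s).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

__all__ = [
    "ProcessParams",
    "SimConfig",
    "TaskDesign",
    "ModulationSpec",
    "PARAM_BOUNDS",
    "MODULATION_FREE_PARAMS",
]

#: Search boxes used by the fitting routines; envelope of plausible values
#: for each parameter with headroom.
PARAM_BOUNDS = {
    "a": (0.05, 1.5),
    "tr": (0.0, 0.5),
    "v_e": (0.0, 5.0),
    "v_b": (0.0, 5.0),
    "xb": (0.0, 5.0),
    "sso": (0.0, 0.3),
}

#: The four contextual-modulation variants: which execution parameters are
#: left free to vary across conditions.
MODULATION_FREE_PARAMS = {
    "drift": ("v_e",),
    "onset": ("tr",),
    "drift_onset": ("v_e", "tr"),
    "bound": ("a",),
    "none": (),
}


@dataclass(frozen=True)
class ProcessParams:
    """Diffusion/race parameters for a single condition.

    Parameters
    ----------
    a : float
        Execution boundary height (evidence units, > 0).
    tr : float
        Onset delay of the execution process (s, >= 0).  Lumps pre- and
        post-decisional delays.
    v_e : float
        Execution drift rate (evidence/s).
    v_b : float
        Braking drift rate magnitude (evidence/s, >= 0).  The dependent
        process model applies it with a negative sign (the braking
        accumulator descends toward 0); the independent and interactive
        race models apply it positively.
    xb : float
        Dynamic-gain coefficient (1/s, >= 0).  The execution accumulator
        is multiplied by the urgency signal gamma(t) = cosh(xb * (t - tr)).
    sigma : float
        Diffusion constant (> 0).  Default 0.1, the conventional
        diffusion-model scaling constant.
    sso : float, optional
        Stop-signal registration delay (s, >= 0); used only by the
        interactive race model.
    """

    a: float
    tr: float
    v_e: float
    v_b: float = 0.0
    xb: float = 0.0
    sigma: float = 0.1
    sso: Optional[float] = None

    def __post_init__(self) -> None:
        vals = [self.a, self.tr, self.v_e, self.v_b, self.xb, self.sigma]
        if self.sso is not None:
            vals.append(self.sso)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("all process parameters must be finite")
        if self.a <= 0:
            raise ValueError(f"boundary height a must be > 0, got {self.a}")
        if self.sigma <= 0:
            raise ValueError(f"diffusion constant sigma must be > 0, got {self.sigma}")
        if self.tr < 0:
            raise ValueError(f"onset delay tr must be >= 0, got {self.tr}")
        if self.xb < 0:
            raise ValueError(f"gain coefficient xb must be >= 0, got {self.xb}")
        if self.v_b < 0:
            raise ValueError(
                "v_b is stored as a magnitude (>= 0); the model applies the sign"
            )
        if self.sso is not None and self.sso < 0:
            raise ValueError(f"sso must be >= 0, got {self.sso}")

    def replace(self, **kwargs) -> "ProcessParams":
        return replace(self, **kwargs)

    def as_dict(self) -> dict:
        d = {
            "a": self.a,
            "tr": self.tr,
            "v_e": self.v_e,
            "v_b": self.v_b,
            "xb": self.xb,
            "sigma": self.sigma,
        }
        if self.sso is not None:
            d["sso"] = self.sso
        return d


@dataclass(frozen=True)
class SimConfig:
    """Numerical configuration for Euler-Maruyama trial simulation."""

    dt: float = 0.001
    deadline: float = 0.650
    seed: int = 0
    n_trials: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.dt <= 0.005):
            raise ValueError(f"dt must be in (0, 0.005], got {self.dt}")
        if self.deadline <= 0:
            raise ValueError("deadline must be positive")
        if self.n_trials < 0:
            raise ValueError("n_trials must be >= 0")

    @property
    def n_steps(self) -> int:
        """Number of integration steps covering [0, deadline]."""
        return int(round(self.deadline / self.dt))

    def replace(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TaskDesign:
    """Trial-structure constants for a reactive or proactive experiment.

    The reactive design is a stop-signal paradigm: five stop-signal delays
    (SSDs) between 200 and 400 ms, a 650 ms response deadline, and 50%
    stop trials.  The proactive design cues the go probability on each
    trial (six levels, 0-100%), uses a single late 450 ms SSD, and a
    555 ms deadline; withholding arises from the execution process failing
    to reach the boundary in time.
    """

    kind: str  # "reactive" | "proactive"
    ssds: Tuple[float, ...]
    deadline: float
    target_time: float = 0.500
    cues: Tuple[float, ...] = ()
    stop_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("reactive", "proactive"):
            raise ValueError(f"unknown task kind {self.kind!r}")
        if any(s >= self.deadline for s in self.ssds):
            raise ValueError("all stop-signal delays must precede the deadline")
        if any(not (0 <= c <= 1) for c in self.cues):
            raise ValueError("go-probability cues must lie in [0, 1]")
        if not (0 <= self.stop_fraction <= 1):
            raise ValueError("stop_fraction must lie in [0, 1]")

    @classmethod
    def reactive(cls) -> "TaskDesign":
        return cls(
            kind="reactive",
            ssds=(0.200, 0.250, 0.300, 0.350, 0.400),
            deadline=0.650,
        )

    @classmethod
    def proactive(cls) -> "TaskDesign":
        return cls(
            kind="proactive",
            ssds=(0.450,),
            deadline=0.555,
            cues=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
            stop_fraction=0.0,
        )


@dataclass(frozen=True)
class ModulationSpec:
    """Which race model is simulated/fit and how context modulates it.

    ``free_params`` is the subset of execution parameters allowed to vary
    across conditions (one of the variants in MODULATION_FREE_PARAMS);
    ``conditions`` are the condition labels (e.g. baseline/caution for the
    reactive task, or the six go-probability cues for the proactive task).
    """

    model_kind: str  # "dpm" | "independent" | "interactive"
    free_params: Tuple[str, ...] = ()
    conditions: Tuple[str, ...] = ("pooled",)

    def __post_init__(self) -> None:
        if self.model_kind not in ("dpm", "independent", "interactive"):
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if tuple(sorted(self.free_params)) not in {
            tuple(sorted(v)) for v in MODULATION_FREE_PARAMS.values()
        }:
            raise ValueError(
                f"free_params {self.free_params!r} is not one of the supported "
                "modulation variants (drift, onset, drift+onset, bound, none)"
            )

    @property
    def modulation(self) -> str:
        for name, ps in MODULATION_FREE_PARAMS.items():
            if tuple(sorted(ps)) == tuple(sorted(self.free_params)):
                return name
        raise AssertionError("unreachable")
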