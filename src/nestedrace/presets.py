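"""Canonical parameter regimes for the stopping models.

These are representative best-fit parameter sets for healthy adults on
the reactive stop-signal task (five SSDs, 650 ms deadline) and the
proactive go-probability task (six cues, 555 ms deadline).  They serve
as simulation defaults and as ground truth in parameter- and
model-recovery studies.  Units: a in evidence units, tr and sso in
seconds, drift rates in evidence/s, xb in 1/s; v_b is stored as a
magnitude (the dependent process model applies it negatively).
"""
from __future__ import annotations

from typing import Dict, List

from .params import ProcessParams, TaskDesign

__all__ = [
    "REACTIVE_PARAMS",
    "REACTIVE_MODULATED",
    "PROACTIVE_PARAMS",
    "proactive_params_by_cue",
]

#: Flat (single-condition) reactive parameter sets per race model.
REACTIVE_PARAMS: Dict[str, ProcessParams] = {
    "dpm": ProcessParams(a=0.534, tr=0.174, v_e=1.266, v_b=0.990, xb=0.878),
    "independent": ProcessParams(a=0.250, tr=0.338, v_e=1.127, v_b=1.269, xb=1.52),
    "interactive": ProcessParams(
        a=0.445, tr=0.220, v_e=1.195, v_b=3.023, xb=1.474, sso=0.197
    ),
}

#: Contextual-modulation parameter sets for the reactive task under the
#: dependent process model: baseline (B) vs caution (C) conditions.
REACTIVE_MODULATED: Dict[str, Dict[str, ProcessParams]] = {
    "drift": {
        "baseline": ProcessParams(a=0.536, tr=0.178, v_e=1.289, v_b=0.984, xb=0.877),
        "caution": ProcessParams(a=0.536, tr=0.178, v_e=1.243, v_b=0.984, xb=0.877),
    },
    "onset": {
        "baseline": ProcessParams(a=0.531, tr=0.171, v_e=1.236, v_b=0.960, xb=0.893),
        "caution": ProcessParams(a=0.531, tr=0.180, v_e=1.236, v_b=0.960, xb=0.893),
    },
    "drift_onset": {
        "baseline": ProcessParams(a=0.538, tr=0.173, v_e=1.269, v_b=0.989, xb=0.858),
        "caution": ProcessParams(a=0.538, tr=0.178, v_e=1.247, v_b=0.989, xb=0.858),
    },
    "bound": {
        "baseline": ProcessParams(a=0.525, tr=0.178, v_e=1.268, v_b=0.984, xb=0.878),
        "caution": ProcessParams(a=0.551, tr=0.178, v_e=1.268, v_b=0.984, xb=0.878),
    },
}

#: Proactive modulation models: constants shared across cues plus the
#: free parameter's value at each go-probability cue (0..100%).
PROACTIVE_PARAMS: Dict[str, dict] = {
    "drift": {
        "constants": {"a": 0.487, "tr": 0.292, "xb": 1.563},
        "free": "v_e",
        "values": (1.411, 1.562, 1.683, 1.761, 1.880, 1.925),
    },
    "onset": {
        "constants": {"a": 0.628, "v_e": 1.42, "xb": 0.641},
        "free": "tr",
        "values": (0.182, 0.161, 0.134, 0.117, 0.084, 0.076),
    },
    "drift_onset": {
        "constants": {"a": 0.06, "xb": 1.468},
        "free": ("v_e", "tr"),
        "values": (
            (0.831, 0.515),
            (0.970, 0.506),
            (0.968, 0.492),
            (0.979, 0.479),
            (0.932, 0.451),
            (1.079, 0.463),
        ),
    },
    "bound": {
        "constants": {"tr": 0.272, "v_e": 0.914, "xb": 0.913},
        "free": "a",
        "values": (0.379, 0.344, 0.305, 0.281, 0.246, 0.236),
    },
}


def proactive_params_by_cue(modulation: str) -> List[ProcessParams]:
    """Per-cue parameter sets for a proactive modulation model, ordered as
    the cues of ``TaskDesign.proactive()`` (0% .. 100% go probability)."""
    entry = PROACTIVE_PARAMS[modulation]
    free = entry["free"]
    out = []
    for v in entry["values"]:
        d = dict(entry["constants"])
        if isinstance(free, tuple):
            d.update(dict(zip(free, v)))
        else:
            d[free] = v
        d.setdefault("a", 0.5)
        d.setdefault("tr", 0.0)
        d.setdefault("v_e", 1.0)
        out.append(ProcessParams(**d))
    return out
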