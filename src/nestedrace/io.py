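"""On-disk formats: trial CSVs, YAML configs, JSON results.

Times are stored in seconds everywhere.  Floats round-trip bit-exactly
via 17-significant-digit formatting.  Every result artifact embeds the
seed and a configuration hash so it can be regenerated.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd
import yaml

from .models import TRIAL_COLUMNS
from .params import ProcessParams

__all__ = [
    "read_trials",
    "write_trials",
    "load_yaml",
    "dump_json",
    "config_hash",
    "params_from_mapping",
]

_FLOAT_FMT = "%.17g"


class TrialSchemaError(ValueError):
    """A trial CSV violates the schema; the message lists offending rows."""


def read_trials(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a trial table CSV.

    Schema: subject, condition, task (reactive|proactive), trial_type
    (go|stop), ssd (s or empty), cue (fraction or empty), response (0|1),
    rt (s, present iff response=1).  Malformed rows are reported with
    their line numbers.
    """
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise TrialSchemaError(f"{path}: missing columns {missing}")
    problems = []
    for idx, row in table.iterrows():
        line = idx + 2  # header is line 1
        if row["task"] not in ("reactive", "proactive"):
            problems.append(f"line {line}: unknown task {row['task']!r}")
        if row["trial_type"] not in ("go", "stop"):
            problems.append(f"line {line}: unknown trial_type {row['trial_type']!r}")
        if row["response"] not in (0, 1):
            problems.append(f"line {line}: response must be 0 or 1")
        has_rt = np.isfinite(row["rt"]) if not pd.isna(row["rt"]) else False
        if row["response"] == 1 and not has_rt:
            problems.append(f"line {line}: response=1 requires an rt")
        if row["response"] == 0 and has_rt:
            problems.append(f"line {line}: response=0 must not carry an rt")
        if row["task"] == "reactive" and not pd.isna(row["cue"]):
            problems.append(f"line {line}: reactive trials must not carry a cue")
    if problems:
        raise TrialSchemaError(f"{path}: " + "; ".join(problems[:20]))
    rts = table["rt"].dropna()
    if len(rts) and rts.max() > 10:
        warnings.warn(
            f"{path}: RT values exceed 10 — data may be in milliseconds; "
            "times are expected in seconds (no conversion applied)",
            UserWarning,
        )
    return table[TRIAL_COLUMNS]


def write_trials(table: pd.DataFrame, path: Union[str, Path]) -> Path:
    """Write a trial table CSV (17-significant-digit floats); returns path."""
    path = Path(path)
    table[TRIAL_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def load_yaml(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return out


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def dump_json(obj: Mapping, path: Union[str, Path], seed=None, config=None) -> Path:
    """Write a JSON result embedding reproducibility provenance."""
    path = Path(path)
    out = dict(obj)
    if seed is not None:
        out.setdefault("provenance", {})["seed"] = seed
    if config is not None:
        out.setdefault("provenance", {})["config_hash"] = config_hash(config)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, default=_json_default)
    return path


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def params_from_mapping(d: Mapping) -> ProcessParams:
    """Build ProcessParams from a plain mapping (e.g. parsed YAML)."""
    allowed = {"a", "tr", "v_e", "v_b", "xb", "sigma", "sso"}
    unknown = set(d) - allowed
    if unknown:
        raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
    return ProcessParams(**{k: float(v) for k, v in d.items()})
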