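"""Run configuration: strict key/value schema with field-level validation.

Configs are flat YAML (or CLI overrides); unknown keys are rejected with a
closest-match suggestion, and cross-field constraints (odd window length,
probabilities in range) are enforced before any stage runs. Every run writes
its fully resolved configuration next to its outputs so a completed run can
be reproduced from that file alone.
"""

from __future__ import annotations

import difflib
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__


class ConfigError(ValueError):
    pass


def _positive(x) -> bool:
    return x > 0


def _fraction(x) -> bool:
    return 0 <= x <= 1


def _odd(x) -> bool:
    return x % 2 == 1


#: key -> (type, default, validator or None, description)
SCHEMA: dict[str, tuple[type, Any, Any, str]] = {
    "seed": (int, 0, None, "root random seed; split deterministically per stage"),
    "l": (int, 17, _odd, "window length (odd)"),
    "mode": (str, "joint", lambda v: v in ("joint", "sequence_only", "error_only"),
             "model branches"),
    "epochs": (int, 10, _positive, "max training epochs"),
    "batch_size": (int, 512, _positive, "mini-batch size"),
    "learning_rate": (float, 0.00125, _positive, "Adam learning rate"),
    "patience": (int, 3, _positive, "early-stopping patience (epochs)"),
    "gamma": (float, 0.83, _fraction, "P(read unmodified | position methylated)"),
    "epsilon": (float, 0.05, _fraction, "P(read modified | position unmethylated)"),
    "method": (str, "bayes", lambda v: v in ("bayes", "threshold", "mean"),
               "position caller"),
    "threshold": (float, 0.2, _fraction, "fraction for the threshold caller"),
    "min_coverage": (int, 1, _positive, "minimum reads per position"),
    "prior_meth": (float, 0.5, lambda v: 0 < v < 1, "prior P(s=1)"),
    "n_reads": (int, 1000, _positive, "simulated reads"),
    "coverage": (int, 30, _positive, "simulated reads per position"),
    "methylation_proportion": (float, 0.5, _fraction, "simulated per-position proportion"),
    "signal_shift": (float, 2.0, lambda v: v >= 0, "methylation current shift (SD units)"),
    "preset": (str, "separable", lambda v: v in ("separable", "hard", "null"),
               "simulation preset"),
    "motif": (str, "CG", lambda v: len(v) >= 1, "target motif"),
    "target_offset": (int, 0, lambda v: v >= 0, "index of target base within motif"),
}


@dataclass
class RunConfig:
    values: dict[str, Any] = field(default_factory=dict)

    def __getattr__(self, key: str):
        try:
            return self.__dict__["values"][key]
        except KeyError:
            raise AttributeError(key)

    def hash(self) -> str:
        payload = json.dumps(self.values, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def dump(self, path: str | Path) -> None:
        doc = dict(self.values)
        doc["version"] = __version__
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def validate_config(raw: dict[str, Any] | None) -> RunConfig:
    """Resolve defaults, reject unknown keys, enforce constraints."""
    raw = dict(raw or {})
    raw.pop("version", None)
    errors = []
    resolved: dict[str, Any] = {}
    for key, value in raw.items():
        if key not in SCHEMA:
            hint = difflib.get_close_matches(key, SCHEMA, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            errors.append(f"unknown key {key!r}{suffix}")
            continue
        typ, _default, check, desc = SCHEMA[key]
        try:
            value = typ(value)
        except (TypeError, ValueError):
            errors.append(f"{key}: expected {typ.__name__}, got {value!r}")
            continue
        if check is not None and not check(value):
            errors.append(f"{key}: invalid value {value!r} ({desc})")
            continue
        resolved[key] = value
    if errors:
        raise ConfigError("; ".join(errors))
    for key, (typ, default, _check, _desc) in SCHEMA.items():
        resolved.setdefault(key, default)
    if resolved["target_offset"] >= len(resolved["motif"]):
        raise ConfigError("target_offset: must index into motif")
    return RunConfig(values=resolved)


def load_config(path: str | Path | None, overrides: dict[str, Any] | None = None) -> RunConfig:
    raw: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a key/value mapping")
        raw.update(loaded)
    for k, v in (overrides or {}).items():
        if v is not None:
            raw[k] = v
    return validate_config(raw)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed (< 2^31)."""
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)
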