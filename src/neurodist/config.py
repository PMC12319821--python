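"""Pipeline configuration: YAML with a declarative schema.

The schema is the nested DEFAULTS tree plus RULES range checks.  Validation
fills defaults, rejects unknown keys, and range-checks every numeric
parameter, so a stage never starts from a malformed configuration.
"""

from __future__ import annotations

import copy
import hashlib
import json
import re
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "validate_config", "config_hash", "parse_radius"]

SCHEMA_VERSION = 1

DEFAULTS: dict = {
    "schema_version": SCHEMA_VERSION,
    "seed": 0,
    "out_dir": "neurodist_out",
    "design": {"n_superordinate": 2, "n_basic_per_super": 3, "n_exemplars": 10},
    "simulate": {
        "enabled": True,
        "n_subjects": 8,
        "n_runs": 10,
        "n_voxels": 100,
        "super_effect": 1.5,
        "basic_effect": 0.5,
        "exemplar_sd": 0.3,
        "exemplar_axis_sd": 0.4,
        "run_noise_sd": 1.0,
    },
    "rts": {
        "rt_intercept": 0.7,
        "rt_slope": 0.15,
        "rt_noise_sd": 0.15,
        "n_trials_per_scene": 24,
        "accuracy_rate": 0.8,
        "n_rt_subjects": 30,
        "tasks": {"categorization": -1, "interference": 1},
    },
    "decode": {
        "enabled": True,
        "n_repeats": 20,
        "schemes": ["superordinate", "basic"],
    },
    "distances": {"enabled": True, "reliability_splits": 100},
    "searchlight": {
        "enabled": False,
        "radius": "2vox",
        "grid_shape": [8, 8, 8],
        "n_repeats": 5,
        "statistic": "decode-super",
        "effect_size": 1.5,
        "noise_sd": 1.0,
        "min_voxels": 2,
    },
    "commonality": {
        "enabled": True,
        "n_layers": 6,
        "peak_layer": 3,
        "n_features": 80,
        "pool_size": 120,
        "feature_noise_sd": 0.3,
        "n_components": 50,
        "n_boot": 2000,
    },
    "group": {"enabled": True, "n_perm": 2000, "fdr_q": 0.05},
}

# (path regex, check, description)
RULES: list[tuple[str, object, str]] = [
    (r"seed$", lambda v: isinstance(v, int) and 0 <= v < 2**31, "integer in [0, 2^31)"),
    (r"design\.n_\w+$", lambda v: isinstance(v, int) and v >= 1, ">= 1"),
    (r"simulate\.n_subjects$", lambda v: isinstance(v, int) and v >= 2, ">= 2"),
    (r"simulate\.n_runs$", lambda v: isinstance(v, int) and v >= 5, ">= 5"),
    (r"simulate\.n_voxels$", lambda v: isinstance(v, int) and v >= 2, ">= 2"),
    (r"simulate\.\w+_(effect|sd)$", lambda v: v >= 0, ">= 0"),
    (r"rts\.rt_intercept$", lambda v: v > 0, "> 0"),
    (r"rts\.accuracy_rate$", lambda v: 0 < v <= 1, "in (0, 1]"),
    (r"rts\.n_\w+$", lambda v: isinstance(v, int) and v >= 1, ">= 1"),
    (r"rts\.tasks\.\w+$", lambda v: v in (-1, 1), "task sign -1 or +1"),
    (r"\w+\.n_repeats$", lambda v: isinstance(v, int) and v >= 1, ">= 1"),
    (r"\w+\.n_(perm|boot)$", lambda v: isinstance(v, int) and v >= 100, ">= 100"),
    (r"group\.fdr_q$", lambda v: 0 < v < 1, "in (0, 1)"),
    (r"commonality\.n_(layers|features|components)$",
     lambda v: isinstance(v, int) and v >= 1, ">= 1"),
    (r"commonality\.peak_layer$", lambda v: v is None or (isinstance(v, int) and v >= 1),
     ">= 1 or null"),
    (r"searchlight\.min_voxels$", lambda v: isinstance(v, int) and v >= 1, ">= 1"),
]

_RADIUS_RE = re.compile(r"^\s*([0-9.]+)\s*(vox|mm)?\s*$")


def parse_radius(value) -> tuple[float, str]:
    """Parse a radius given as a number or a string like '4vox' / '8mm'.

    Returns (magnitude, unit) with unit 'vox' or 'mm' ('vox' when bare).
    """
    if isinstance(value, (int, float)):
        return float(value), "vox"
    m = _RADIUS_RE.match(str(value))
    if not m:
        raise ValueError(f"cannot parse radius {value!r}; use e.g. 4, '4vox' or '8mm'")
    return float(m.group(1)), m.group(2) or "vox"


def _merge(defaults: dict, user: dict, path: str, errors: list[str]) -> dict:
    out = copy.deepcopy(defaults)
    for key, val in (user or {}).items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            errors.append(f"unknown key: {here}")
            continue
        if isinstance(defaults[key], dict) and key != "tasks":
            if not isinstance(val, dict):
                errors.append(f"{here} must be a mapping")
            else:
                out[key] = _merge(defaults[key], val, here, errors)
        else:
            out[key] = val
    return out


def _check_rules(cfg: dict, path: str, errors: list[str]) -> None:
    for key, val in cfg.items():
        here = f"{path}.{key}" if path else key
        if isinstance(val, dict):
            _check_rules(val, here, errors)
            continue
        for pattern, check, desc in RULES:
            if re.search(pattern, here):
                try:
                    ok = check(val)
                except TypeError:
                    ok = False
                if not ok:
                    errors.append(f"{here}={val!r} out of range (expected {desc})")
                break


def validate_config(source: str | Path | dict | None = None) -> dict:
    """Load and validate a pipeline config; fill defaults.

    ``source`` may be a YAML path, a dict, or None/empty (full defaults).
    Unknown keys and out-of-range values raise ValueError naming the key.
    """
    if source is None:
        user: dict = {}
    elif isinstance(source, dict):
        user = source
    else:
        text = Path(source).read_text()
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise ValueError("config file must contain a YAML mapping")

    errors: list[str] = []
    cfg = _merge(DEFAULTS, user, "", errors)
    if cfg.get("schema_version") != SCHEMA_VERSION:
        errors.append(f"unsupported schema_version {cfg.get('schema_version')!r}")
    _check_rules(cfg, "", errors)
    try:
        parse_radius(cfg["searchlight"]["radius"])
    except ValueError as e:
        errors.append(str(e))
    if cfg["commonality"]["peak_layer"] is not None and \
            cfg["commonality"]["peak_layer"] > cfg["commonality"]["n_layers"]:
        errors.append("commonality.peak_layer exceeds commonality.n_layers")
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable hash of a validated config (out_dir excluded: location-free)."""
    payload = {k: v for k, v in cfg.items() if k != "out_dir"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode("utf-8")
    ).hexdigest()
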