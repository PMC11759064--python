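"""Config validation: flat YAML file with per-stage sections, filled defaults,
cross-field constraints, and idempotent normalization."""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Union

import yaml

DEFAULTS: dict[str, dict[str, Any]] = {
    "build": {
        "n_chains": 100,
        "chain_length": 20,
        "phi_p": 1.0,
        "phi_s": 0.0,
        "phi_g": 0.0,
        "target_density": 0.85,
        "sticker_interval": 0,
        "sticker_strength": 1.0,
        "crosslink_mode": "none",
        "angle_k": None,
        "angle_theta0": 180.0,
        "seed": 0,
    },
    "engine": {
        "dt": 0.005,
        "temperature": 1.0,
        "damping": 1.0,
        "seed": 0,
        "n_steps": 200000,
        "sample_stride": 4,
        "frame_stride": 2000,
        "shifted_force": False,
    },
    "shear": {
        "gamma0": 0.1,
        "omega": 0.5,
        "n_cycles": 8,
    },
    "rheology": {
        "lags_per_block": 16,
        "blocks_m": 2,
        "n_modes": None,
        "ndiff_weight": 1.0 / 6.0,
        "gk_t_min": 0.5,
    },
    "aging": {
        "evap_rate": 10.0,
        "boundary_slab": 0.5,
        "shrink_mode": "wall_follow",
        "duration": 100.0,
        "record_every": 5.0,
        "n_bins": 40,
        "shell_threshold": 0.9,
    },
    "phase": {
        "temperatures": [1.6, 1.8, 2.0, 2.1],
        "n_bins": 60,
        "beta": 0.325,
    },
}


class ConfigError(ValueError):
    def __init__(self, problems: list[str]):
        super().__init__("invalid config:\n  " + "\n  ".join(problems))
        self.problems = problems


def validate_config(source: Union[str, Path, dict, None]) -> dict:
    """Normalize a config: fill defaults, reject unknown keys, check ranges.

    ``source`` may be a YAML path, a dict, or None/empty (full defaults).
    Normalization is idempotent: normalize(normalize(c)) == normalize(c).
    """
    if source is None:
        user: dict = {}
    elif isinstance(source, dict):
        user = copy.deepcopy(source)
    else:
        text = Path(source).read_text()
        user = yaml.safe_load(text) or {}
    problems: list[str] = []
    cfg = copy.deepcopy(DEFAULTS)
    for section, values in user.items():
        if section not in cfg:
            problems.append(f"unknown section [{section}]")
            continue
        if values is None:
            continue
        for key, val in values.items():
            if key not in cfg[section]:
                problems.append(f"unknown key {section}.{key}")
            else:
                cfg[section][key] = val
    if problems:
        raise ConfigError(problems)

    e = cfg["engine"]
    if not 0 < e["dt"] <= 0.05:
        problems.append(f"engine.dt = {e['dt']} outside (0, 0.05] tau")
    if e["temperature"] <= 0:
        problems.append("engine.temperature must be positive")
    if e["damping"] < 0:
        problems.append("engine.damping must be non-negative")
    s = cfg["shear"]
    if s["gamma0"] <= 0:
        problems.append("shear.gamma0 must be positive")
    if s["omega"] * e["dt"] > 0.1:
        problems.append("shear.omega * engine.dt exceeds 0.1 rad/step")
    b = cfg["build"]
    if abs(b["phi_p"] + b["phi_s"] + b["phi_g"] - 1.0) > 1e-9:
        problems.append("build volume fractions must sum to 1")
    if b["target_density"] > 1.2:
        problems.append("build.target_density above 1.2 is not packable")
    a = cfg["aging"]
    if a["evap_rate"] < 0:
        problems.append("aging.evap_rate must be non-negative")
    if a["boundary_slab"] <= 0:
        problems.append("aging.boundary_slab must be positive")
    if problems:
        raise ConfigError(problems)
    return cfg
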