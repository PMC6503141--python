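"""Nested pipeline configuration with strict key validation.

A configuration is a plain nested dict; :func:`resolve_config` merges user
input (YAML file and/or dict) over the defaults, rejecting unknown keys so
typos fail loudly. Every pipeline run writes back the fully resolved
configuration for reproducibility.
"""

from __future__ import annotations

import copy

import yaml

DEFAULTS = {
    "run": {
        "seed": 0,
        "out_dir": "bonedyn_out",
        "verbosity": "info",
    },
    "fixtures": {
        "femur": {
            "shaft_length": 0.30,
            "shaft_radius": 0.016,
            "neck_length": 0.05,
            "neck_shaft_angle_deg": 125.0,
            "head_radius": 0.024,
            "trochanter_offset": 0.012,
            "cortical_thickness": 0.004,
            "resolution": 2,
        },
        "hu_volume": {
            "noise_sigma": 5.0,
            "spacing_mm": 2.5,
        },
        "squat": {
            "duration": 4.5,
            "depth": None,  # metres; None -> 25% of leg length
            "dt": 0.01,
        },
    },
    "material": {
        "tissue_threshold": 0.6,  # g/cm^3 cortical/trabecular cut
        "law": {
            "e0": 20000e6,
            "a": -5.19,
            "b_coef": -2.30,
            "e_floor": 1e6,
            "poisson": 0.3,
            "mass_density": 1940.0,
        },
    },
    "reduction": {
        "n_modes": 30,
        "zeta": 0.025,
    },
    "msk": {
        "k_p": 400.0,
        "dt_control": 0.01,
        "dt_integrate": 0.001,
        "use_reserves": True,
    },
    "strength": {
        "threshold": 0.04,
        "max_load": 10000.0,
        "n_steps": 20,
    },
    "pipeline": {
        "scenarios": ["native", "C84T67", "C68T34"],
        "transient_dt": 0.005,
    },
}


class ConfigError(ValueError):
    pass


def _merge(base: dict, override: dict, path="") -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{here} must be a mapping")
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


def resolve_config(source=None, overrides: dict = None) -> dict:
    """Merge a YAML file path or dict plus overrides over the defaults."""
    cfg = copy.deepcopy(DEFAULTS)
    if source is not None:
        if isinstance(source, dict):
            data = source
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, data)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def dump_config(cfg: dict, path):
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
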