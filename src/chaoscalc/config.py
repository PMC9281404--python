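"""Configuration defaults, YAML loading and human-duration parsing."""

from __future__ import annotations

import re
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config", "parse_duration"]

#: Package defaults.  Equilibration discards follow the two simulation
#: profiles (coarse-grained: 50 ns; atomistic: 500 ns); time is ps
#: internally throughout.
DEFAULTS = {
    "profile": "cg",
    "t_discard_ps": {"cg": 50_000.0, "atomistic": 500_000.0},
    "n_blocks": 5,
    "tension_source": "recompute",  # or "surften_column"
    "bound_threshold_nm": 1.5,
    "binding_window_ps": 100_000.0,
    "leaflet_offset_nm": 1.03,
    "ti_method": "trapezoid",
}

_DURATION_RE = re.compile(r"^\s*([0-9.]+)\s*(ps|ns|us|ms)?\s*$")
_TO_PS = {"ps": 1.0, "ns": 1e3, "us": 1e6, "ms": 1e9, None: 1.0}


def parse_duration(text: str | float) -> float:
    """Parse ``"50ns"``-style durations into ps (bare numbers are ps)."""
    if isinstance(text, (int, float)):
        return float(text)
    m = _DURATION_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse duration {text!r}")
    return float(m.group(1)) * _TO_PS[m.group(2)]


def load_config(path: str | Path | None = None) -> dict:
    """Defaults overlaid with a YAML config file, when given."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULTS.items()}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, value in user.items():
            if key not in cfg:
                raise KeyError(f"unknown config key {key!r}")
            if isinstance(cfg[key], dict) and isinstance(value, dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg


def default_t_discard(cfg: dict) -> float:
    return float(cfg["t_discard_ps"][cfg["profile"]])
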