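"""Flat INI-style run configuration (``key = value`` under ``[section]``).

The dialect is deliberately diff-able plain text with no code execution.
Unknown sections or keys are rejected so that typos fail loudly, and every
run logs the fully-resolved configuration.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Dict, Optional

__all__ = ["ConfigError", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid, missing or unknown configuration keys."""


_SCHEMA: Dict[str, Dict[str, Any]] = {
    "image": {
        "path": str,
        "band_order": str,
        "resolution_cm_per_px": float,
    },
    "grid": {
        "p": int,
        "q": int,
        "cell_w_m": float,
        "cell_h_m": float,
        "pitch_u_m": float,
        "pitch_v_m": float,
        "origin_px": str,  # "x,y"
        "rotation_deg": float,
        "sequence": str,
    },
    "optimizer": {
        "swarm_density": float,
        "tolerance": float,
        "stall_iterations": int,
        "max_iterations": int,
        "seed": int,
        "bounds_fraction": float,
    },
    "segmentation": {
        "threshold": str,  # "auto" or a float in [-1, 1]
    },
    "evaluation": {
        "success_threshold_cm": float,
    },
    "io": {
        "output_dir": str,
    },
}

_DEFAULTS: Dict[str, Dict[str, Any]] = {
    "image": {"band_order": "rgb", "resolution_cm_per_px": 0.8},
    "grid": {"origin_px": "0,0", "rotation_deg": 0.0, "sequence": "row_major",
             "pitch_u_m": 0.0, "pitch_v_m": 0.0},
    "optimizer": {
        "swarm_density": 8.0,
        "tolerance": 1e-4,
        "stall_iterations": 20,
        "seed": 0,
        "bounds_fraction": 0.5,
    },
    "segmentation": {"threshold": "auto"},
    "evaluation": {},
    "io": {"output_dir": "."},
}


@dataclass
class RunConfig:
    """Parsed configuration: ``cfg["section"]["key"]`` with typed values."""

    sections: Dict[str, Dict[str, Any]]
    source: Optional[Path] = None

    def __getitem__(self, section: str) -> Dict[str, Any]:
        return self.sections.get(section, {})

    def require(self, section: str, key: str) -> Any:
        try:
            return self.sections[section][key]
        except KeyError:
            raise ConfigError(f"missing required config key [{section}] {key}") from None

    def describe(self) -> str:
        lines = []
        for sec in sorted(self.sections):
            lines.append(f"[{sec}]")
            for key in sorted(self.sections[sec]):
                lines.append(f"{key} = {self.sections[sec][key]}")
        return "\n".join(lines)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a config file against the schema."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    parser = configparser.ConfigParser()
    try:
        parser.read(path)
    except configparser.Error as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc

    sections: Dict[str, Dict[str, Any]] = {
        sec: dict(vals) for sec, vals in _DEFAULTS.items()
    }
    for sec in parser.sections():
        if sec not in _SCHEMA:
            raise ConfigError(f"unknown config section [{sec}]")
        for key, raw in parser.items(sec):
            if key not in _SCHEMA[sec]:
                raise ConfigError(f"unknown config key [{sec}] {key}")
            caster = _SCHEMA[sec][key]
            try:
                sections[sec][key] = caster(raw)
            except (TypeError, ValueError):
                raise ConfigError(
                    f"config key [{sec}] {key}: cannot parse {raw!r} as "
                    f"{caster.__name__}"
                ) from None
    return RunConfig(sections=sections, source=path)


def parse_origin(text: str) -> tuple[float, float]:
    parts = [p.strip() for p in str(text).split(",")]
    if len(parts) != 2:
        raise ConfigError(f"origin_px must be 'x,y', got {text!r}")
    return float(parts[0]), float(parts[1])


def parse_threshold(text: str):
    if text == "auto":
        return "auto"
    try:
        return float(text)
    except ValueError:
        raise ConfigError(
            f"segmentation threshold must be 'auto' or a number, got {text!r}"
        ) from None
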