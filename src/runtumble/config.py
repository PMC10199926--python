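"""Configuration files, presets and run manifests.

Config blocks are flat JSON/YAML mappings using the shared key schema
(log_coeff, offset, critical_conc, amplitude, decay_rate, baseline,
slope_a, intercept_l0, lambda0, alpha, b, L, n_walkers, n_steps, burn_in,
seed, mode, init, ...).  The ``paper_defaults`` preset carries the
published fitted constants.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Dict, List, Optional

import yaml

from . import __version__
from .exceptions import ConfigError
from .laws import ConcentrationProfile, JumpConcentrationLaw, PositionJumpLaw

__all__ = ["paper_defaults", "load_config", "RunManifest"]


def paper_defaults() -> Dict[str, Any]:
    """The published fitted constants as one flat config block.

    Includes the printed position-law coefficients (0.063, 12.9) and the
    directional-bias estimate 0.295, plus the reference simulation setup
    (lambda0 = 1, alpha = 0.01, L = 100, N = 2000 walkers).
    """
    return {
        # concentration -> jump length law
        "log_coeff": -3.5,
        "offset": 15.5,
        "critical_conc": 0.33,
        # concentration profile
        "amplitude": 2.0,
        "decay_rate": 0.018,
        "baseline": 0.33,
        # position law (printed coefficients)
        "slope_a": 0.063,
        "intercept_l0": 12.9,
        # directional bias estimate
        "b": 0.295,
        # reference walker simulation
        "lambda0": 1.0,
        "alpha": 0.01,
        "beta_values": [0.001, 0.01, 0.05],
        "L": 100.0,
        "n_walkers": 2000,
        "n_steps": 5000,
        "burn_in": 2500,
        "seed": 0,
        "mode": "angular",
        "init": "uniform",
    }


def jump_law_from_config(cfg: Dict[str, Any]) -> JumpConcentrationLaw:
    return JumpConcentrationLaw(
        log_coeff=cfg.get("log_coeff", -3.5),
        offset=cfg.get("offset", 15.5),
        critical_conc=cfg.get("critical_conc", 0.33),
    )


def profile_from_config(cfg: Dict[str, Any]) -> ConcentrationProfile:
    return ConcentrationProfile(
        amplitude=cfg.get("amplitude", 2.0),
        decay_rate=cfg.get("decay_rate", 0.018),
        baseline=cfg.get("baseline", 0.33),
    )


def position_law_from_config(cfg: Dict[str, Any]) -> PositionJumpLaw:
    return PositionJumpLaw(
        slope_a=cfg.get("slope_a", 0.063), intercept_l0=cfg.get("intercept_l0", 12.9)
    )


def load_config(path) -> Dict[str, Any]:
    """Read a JSON or YAML config block into a flat dict."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    text = p.read_text()
    try:
        if p.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except Exception as exc:  # noqa: BLE001
        raise ConfigError(f"cannot parse config {p}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"config {p} must be a mapping")
    return data


@dataclass
class RunManifest:
    """Provenance of one CLI run: config + seed reproduce it byte-identically."""

    command: str
    config: Dict[str, Any]
    seed: Optional[int]
    outputs: List[str] = field(default_factory=list)
    version: str = __version__
    python: str = platform.python_version()
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")
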