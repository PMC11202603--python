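"""Project configuration: validated YAML with defaults and content hashing.

A config file is a YAML mapping with optional sections ``phantom``,
``probe``, ``network``, ``training`` and ``stats`` plus ``master_seed`` and
``profile``.  Unknown keys anywhere are rejected with their full path, so a
typo never silently falls back to a default.  Every run stamps
``config_hash`` into its outputs; together with the master seed it pins the
run exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .acoustics import ProbeConfig
from .errors import ConfigurationError
from .network import NetworkConfig, reduced_network_config
from .phantom import PhantomSpec
from .pipeline import TrainConfig

__all__ = ["ProjectConfig", "load_config", "save_config", "config_hash"]

_SECTIONS = {
    "phantom": PhantomSpec,
    "probe": ProbeConfig,
    "network": NetworkConfig,
    "training": TrainConfig,
}


@dataclass
class StatsConfig:
    rho_ac_pdff: float = 0.9
    cohort_n: int = 200
    roc_bootstrap: int = 2000


@dataclass
class ProjectConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    probe: ProbeConfig = field(default_factory=ProbeConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    master_seed: int = 0
    profile: str = "reduced"  # "reduced" | "full"

    def hash(self) -> str:
        return config_hash(self)


def _coerce(value, target):
    """Round-trip YAML scalars/lists into the dataclass field's shape."""
    if isinstance(target, tuple) and isinstance(value, list):
        return tuple(_coerce(v, target[0] if target else None) for v in value)
    return value


def _apply(section_obj, data: dict, path: str):
    names = {f.name: f for f in dataclasses.fields(section_obj)}
    for key, val in data.items():
        if key not in names:
            raise ConfigurationError(f"unknown key '{path}.{key}'")
        cur = getattr(section_obj, key)
        if isinstance(val, dict) and dataclasses.is_dataclass(cur):
            _apply(cur, val, f"{path}.{key}")
        else:
            setattr(section_obj, key, _coerce(val, cur))
    return section_obj


def load_config(path: str | Path | None = None, text: str | None = None) -> ProjectConfig:
    """Parse and validate a YAML config; an empty file yields all defaults."""
    if text is None:
        if path is None:
            raise ConfigurationError("need a path or text")
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"config file not found: {p}")
        text = p.read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    cfg = ProjectConfig()
    for key, val in raw.items():
        if key == "master_seed":
            cfg.master_seed = int(val)
        elif key == "profile":
            if val not in ("reduced", "full"):
                raise ConfigurationError(f"profile must be 'reduced' or 'full', got {val!r}")
            cfg.profile = val
        elif key in _SECTIONS or key == "stats":
            section = getattr(cfg, key)
            if not isinstance(val, dict):
                raise ConfigurationError(f"section '{key}' must be a mapping")
            _apply(section, val, key)
        else:
            raise ConfigurationError(f"unknown key '{key}'")
    if cfg.profile == "reduced":
        _apply_reduced_profile(cfg, raw)
    # Re-validate specs whose __post_init__ carries the invariants.
    cfg.phantom = dataclasses.replace(cfg.phantom)
    cfg.probe = dataclasses.replace(cfg.probe)
    return cfg


def _apply_reduced_profile(cfg: ProjectConfig, raw: dict) -> None:
    """Desk-scale defaults (coarser grid, compact net, small splits).

    Only fields the user did not set explicitly are overridden.
    """
    user_ph = raw.get("phantom", {})
    if "grid_shape" not in user_ph:
        cfg.phantom.grid_shape = (320, 128)
    if "cell_size" not in user_ph:
        cfg.phantom.cell_size = 0.25
    user_net = raw.get("network", {})
    if not user_net:
        cfg.network = reduced_network_config(seed=cfg.network.seed)
    user_tr = raw.get("training", {})
    reduced_training = {"n_train": 320, "n_val": 40, "n_test": 40,
                        "lr": 1.5e-3, "batch_size": 16, "max_epochs": 150,
                        "patience": 30}
    for k, v in reduced_training.items():
        if k not in user_tr:
            setattr(cfg.training, k, v)


def save_config(cfg: ProjectConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_as_dict(cfg), sort_keys=True))


def _as_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_as_dict(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _as_dict(v) for k, v in obj.items()}
    return obj


def config_hash(cfg: ProjectConfig) -> str:
    """Stable short hash of the fully-resolved configuration."""
    canon = json.dumps(_as_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
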