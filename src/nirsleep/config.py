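"""Run configuration: YAML sections per pipeline stage, unknown keys rejected."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from ._cnn import CNNConfig
from .quality import QualityConfig
from .synthetic import SimulationConfig

SECTIONS = ("simulate", "optics", "quality", "vitals", "features",
            "model", "evaluation")
GLOBAL_KEYS = ("seed", "out_dir", "log_level")


def _check_keys(section: str, data: dict, cls) -> None:
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(
            f"unknown keys {sorted(unknown)} in config section {section!r}; "
            f"allowed: {sorted(allowed)}"
        )


def load_config(path: str | Path) -> dict:
    """Parse and validate a run config; every value not set falls back to the
    documented dataclass default."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    unknown = set(raw) - set(SECTIONS) - set(GLOBAL_KEYS)
    if unknown:
        raise ValueError(f"unknown top-level config keys {sorted(unknown)}; "
                         f"allowed sections: {SECTIONS}, globals: {GLOBAL_KEYS}")
    for section, cls in (("simulate", SimulationConfig), ("quality", QualityConfig),
                         ("model", CNNConfig)):
        if section in raw and raw[section]:
            _check_keys(section, raw[section], cls)
    return raw


def resolved_config(raw: dict, seed: int) -> dict:
    """Fully resolved config (defaults filled in) for run-log provenance."""
    out = {"seed": seed}
    sim = dataclasses.asdict(SimulationConfig(seed=seed, **(raw.get("simulate") or {})))
    out["simulate"] = sim
    out["quality"] = dataclasses.asdict(QualityConfig(**(raw.get("quality") or {})))
    out["model"] = dataclasses.asdict(CNNConfig(**(raw.get("model") or {})))
    for extra in ("optics", "vitals", "features", "evaluation"):
        out[extra] = raw.get(extra) or {}
    return out


def config_hash(resolved: dict) -> str:
    blob = json.dumps(resolved, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
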