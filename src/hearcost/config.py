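"""Run configuration: defaults, YAML loading, and a stable config hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from importlib import resources
from pathlib import Path

import yaml

from .psa import DEFAULT_SEED
from .scaleup import ABSTRACT_STYLE, DEFAULT_N_SCHOOLS_TARGET, RESULTS_STYLE

__all__ = ["RunConfig", "packaged_fixture", "load_config"]


def packaged_fixture(name: str) -> Path:
    """Path to a CSV fixture shipped inside the package."""
    return Path(resources.files("hearcost.fixtures") / name)


@dataclass(frozen=True)
class RunConfig:
    """Everything a full analysis run needs; flags override file values."""

    ledger_path: str = ""
    cascade_path: str = ""
    scenario: str = "model3"
    component_halfwidth: float = 0.20
    economic_halfwidth: float = 0.05
    psa_draws: int = 10_000
    seed: int = DEFAULT_SEED
    n_schools_target: int = DEFAULT_N_SCHOOLS_TARGET
    rounding_convention: str = RESULTS_STYLE
    denominator: str = "any"
    out_dir: str = "hearcost_out"

    def __post_init__(self) -> None:
        if self.component_halfwidth <= 0 or self.economic_halfwidth <= 0:
            raise ValueError("sensitivity halfwidths must be positive")
        if self.psa_draws < 1:
            raise ValueError("psa_draws must be >= 1")
        if self.rounding_convention not in (RESULTS_STYLE, ABSTRACT_STYLE):
            raise ValueError(f"unknown rounding convention {self.rounding_convention!r}")

    def resolved(self) -> "RunConfig":
        """Fill empty paths with the packaged Malindi 2018 fixtures."""
        updates = {}
        if not self.ledger_path:
            updates["ledger_path"] = str(packaged_fixture("malindi_2018.csv"))
        if not self.cascade_path:
            updates["cascade_path"] = str(packaged_fixture("malindi_cascade.csv"))
        return replace(self, **updates) if updates else self

    def config_hash(self) -> str:
        """SHA-256 over the canonical JSON form (first 12 hex digits)."""
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(loaded) - set(RunConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)
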