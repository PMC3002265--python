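"""Scenario configuration: the knobs a run exposes and their defaults.

The two headline switches are ``allocation_unit`` (*country* vs
*regional* cropland scenario) and ``crop_mix_id`` (which of the five
2015 crop-mix matrices to apply).  ``credit_prices`` carries the net
avoided-emission credit prices p − c (currency per Mg CO2e);
``delta_readiness`` is the new-cropland productive-capacity fraction δ
(1 = new land reaches projected capacity by 2015).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import yaml

ALLOCATION_UNITS = ("country", "regional")
CROP_MIX_IDS = ("y2000", "low", "mean", "near2000", "projected2015")


class ConfigError(ValueError):
    """Missing or invalid configuration key."""


@dataclass
class ScenarioConfig:
    scenario_name: str
    allocation_unit: str = "country"
    years: int = 15
    seed: int = 0
    crop_mix_id: str = "y2000"
    credit_prices: list = field(default_factory=lambda: [5.0, 150.0])
    delta_readiness: float = 1.0
    irrigation_strictness: float = 2.0
    irrigation_threshold: float = 0.10
    hdi_developing_cutoff: float = 0.8
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.allocation_unit not in ALLOCATION_UNITS:
            raise ConfigError(
                f"allocation_unit must be one of {ALLOCATION_UNITS}, "
                f"got {self.allocation_unit!r}")
        if self.crop_mix_id not in CROP_MIX_IDS:
            raise ConfigError(
                f"crop_mix_id must be one of {CROP_MIX_IDS}, "
                f"got {self.crop_mix_id!r}")
        if int(self.years) < 1:
            raise ConfigError("years must be ≥ 1")
        self.years = int(self.years)
        if not self.credit_prices:
            raise ConfigError("credit_prices must be non-empty")
        self.credit_prices = [float(p) for p in self.credit_prices]
        if not (0.0 <= self.delta_readiness <= 1.0):
            raise ConfigError("delta_readiness must lie in [0, 1]")
        if self.irrigation_strictness <= 0:
            raise ConfigError("irrigation_strictness must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> ScenarioConfig:
    """Load a YAML or JSON scenario configuration file.

    Unknown keys are rejected; ``scenario_name`` is required; everything
    else takes its documented default.
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") \
        else json.loads(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {f.name for f in fields(ScenarioConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    if "scenario_name" not in data:
        raise ConfigError(f"{path}: missing required key 'scenario_name'")
    return ScenarioConfig(**data)


def save_config(cfg: ScenarioConfig, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
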