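"""Scenario configuration: packaged defaults and YAML loading.

The default configuration reproduces the Germany-2016 worked example
with zero external inputs: calibrated total deaths, the packaged cost
overrides, and burden inputs from the calibrated synthetic tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .burden import GERMANY_2016_TOTAL_DEATHS, LifeTable, MortalityTable
from .dose_response import DEFAULT_ANCHORS, RRRAnchors, SerumModel, serum_model
from .economics import DEFAULT_COST_PER_DEATH, CostModel
from .errors import ConfigurationError

DEFAULT_DOSES: tuple[float, ...] = (400.0, 600.0, 800.0, 1000.0)
DEFAULT_VARIANTS: tuple[str, ...] = ("base", "low20", "high20")

__all__ = ["ScenarioConfig", "load_config", "default_config"]


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to run a scenario grid deterministically."""

    serum: SerumModel = field(default_factory=lambda: serum_model("table5"))
    anchors: RRRAnchors = DEFAULT_ANCHORS
    cost_model: CostModel = field(default_factory=CostModel)
    cost_per_death: float = DEFAULT_COST_PER_DEATH
    total_deaths: float = GERMANY_2016_TOTAL_DEATHS
    #: None -> derived at run time from the burden tables (explicit CSVs
    #: if configured, else the calibrated synthetic defaults).
    total_yll: float | None = None
    mortality_csv: str | None = None
    life_csv: str | None = None
    doses: tuple[float, ...] = DEFAULT_DOSES
    variants: tuple[str, ...] = DEFAULT_VARIANTS
    seed: int = 0

    def load_mortality(self) -> MortalityTable | None:
        return MortalityTable.from_csv(self.mortality_csv) if self.mortality_csv else None

    def load_life(self) -> LifeTable | None:
        return LifeTable.from_csv(self.life_csv) if self.life_csv else None


def default_config(**overrides) -> ScenarioConfig:
    """The packaged Germany-2016 default configuration."""
    return replace(ScenarioConfig(), **overrides) if overrides else ScenarioConfig()


def load_config(path: str | Path) -> ScenarioConfig:
    """Build a ScenarioConfig from a YAML document.

    Any omitted key falls back to the packaged default. See
    ``data/default_config.yaml`` for the schema.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(raw)}")

    kwargs: dict = {}
    if "serum" in raw:
        s = raw["serum"]
        if "slope" in s:
            kwargs["serum"] = SerumModel(
                slope=float(s["slope"]), source_tag=s.get("source", "custom")
            )
        elif "source" in s:
            kwargs["serum"] = serum_model(s["source"])
    if "anchors" in raw:
        kwargs["anchors"] = RRRAnchors(
            points=tuple((float(d), float(r)) for d, r in raw["anchors"])
        )
    if "cost" in raw:
        c = dict(raw["cost"])
        if "cost_overrides" in c:
            c["cost_overrides"] = {
                float(k): float(v) for k, v in c["cost_overrides"].items()
            }
        known = {
            "unit_ingredient_cost",
            "loss_fraction",
            "component_shares",
            "population",
            "cost_overrides",
            "loss_convention",
        }
        unknown = set(c) - known
        if unknown:
            raise ConfigurationError(f"unknown cost keys: {sorted(unknown)}")
        kwargs["cost_model"] = CostModel(**c)
    for key in ("cost_per_death", "total_deaths", "total_yll"):
        if key in raw and raw[key] is not None:
            kwargs[key] = float(raw[key])
    for key in ("mortality_csv", "life_csv"):
        if key in raw and raw[key]:
            kwargs[key] = str(raw[key])
    if "doses" in raw:
        kwargs["doses"] = tuple(float(d) for d in raw["doses"])
    if "variants" in raw:
        kwargs["variants"] = tuple(str(v) for v in raw["variants"])
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    return default_config(**kwargs)
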