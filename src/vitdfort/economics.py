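"""Fortification program costs, savings from prevented deaths, and ratios.

Program costs for the four modeled doses ship as fixed overrides (in
thousand EUR) because the published cost appendix underlying them is not
reproducible from the main-text parameters; a parametric ingredient-cost
formula is provided for other doses/populations. Savings value each
prevented cancer death at a flat end-of-life care cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

from ._rounding import round_half_up_int
from .errors import ConfigurationError, DomainError

CostVariant = Literal["base", "low20", "high20"]

#: +-20% sensitivity scaling applied to the base cost.
VARIANT_SCALE: dict[str, float] = {"base": 1.0, "low20": 0.8, "high20": 1.2}

#: Published base program costs (thousand EUR/year) for the modeled doses.
DEFAULT_COST_OVERRIDES: dict[float, float] = {
    400.0: 15_166.0,
    600.0: 17_493.0,
    800.0: 19_819.0,
    1000.0: 22_146.0,
}

DEFAULT_COMPONENT_SHARES: dict[str, float] = {
    "ingredient": 0.80,
    "marketing": 0.08,
    "monitoring": 0.07,
    "other": 0.05,
}

DEFAULT_COST_PER_DEATH = 40_000.0

__all__ = [
    "CostModel",
    "EconResult",
    "fortification_cost",
    "savings",
    "net_savings",
    "cost_per_life_year",
    "savings_cost_ratio",
    "VARIANT_SCALE",
    "DEFAULT_COST_OVERRIDES",
    "DEFAULT_COMPONENT_SHARES",
    "DEFAULT_COST_PER_DEATH",
]


@dataclass(frozen=True)
class CostModel:
    """Cost structure of a national fortification program.

    ``unit_ingredient_cost`` is EUR per person-year of the ingredient at
    800 IU/day; ``loss_fraction`` is vitamin destroyed during food
    processing. ``loss_convention`` selects how losses inflate required
    production: "divide" (required = delivered / (1 - loss)) or
    "multiply" (required = delivered * (1 + loss)).
    """

    unit_ingredient_cost: float = 0.11
    loss_fraction: float = 0.41
    component_shares: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPONENT_SHARES)
    )
    population: float | None = None
    cost_overrides: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_COST_OVERRIDES)
    )
    loss_convention: Literal["divide", "multiply"] = "divide"

    def __post_init__(self) -> None:
        if abs(sum(self.component_shares.values()) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"component shares must sum to 1, got {dict(self.component_shares)}"
            )
        if not 0 <= self.loss_fraction < 1:
            raise ConfigurationError(
                f"loss fraction must lie in [0, 1), got {self.loss_fraction}"
            )
        if self.population is not None and self.population <= 0:
            raise ConfigurationError(
                f"population must be positive, got {self.population}"
            )
        if self.loss_convention not in ("divide", "multiply"):
            raise ConfigurationError(
                f"unknown loss convention {self.loss_convention!r}"
            )
        if "ingredient" not in self.component_shares:
            raise ConfigurationError("component shares must include 'ingredient'")


@dataclass(frozen=True)
class EconResult:
    """Economic outcome of one scenario (monetary fields in thousand EUR)."""

    cost: int
    savings: int
    net_savings: int
    cost_per_life_year: int
    savings_cost_ratio: float


def _parametric_base_cost(dose_iu: float, model: CostModel) -> float:
    """Ingredient-cost formula scaled up to total program cost (kEUR)."""
    if model.population is None:
        raise ConfigurationError(
            f"no cost override for dose {dose_iu} IU/day and no population "
            "configured for the parametric cost formula"
        )
    ingredient = model.unit_ingredient_cost * (dose_iu / 800.0)
    if model.loss_convention == "divide":
        ingredient /= 1.0 - model.loss_fraction
    else:
        ingredient *= 1.0 + model.loss_fraction
    total_per_person = ingredient / model.component_shares["ingredient"]
    return total_per_person * model.population / 1000.0


def fortification_cost(
    dose_iu: float,
    model: CostModel | None = None,
    variant: CostVariant = "base",
) -> int:
    """Program cost in thousand EUR for a dose under a sensitivity variant.

    The base cost comes from the dose's override when present, otherwise
    from the parametric formula; the variant scales it by 0.8/1.0/1.2
    and the result is rounded half-up to the nearest thousand EUR.
    """
    if dose_iu <= 0:
        raise DomainError(f"dose must be positive, got {dose_iu}")
    if variant not in VARIANT_SCALE:
        raise ConfigurationError(
            f"unknown cost variant {variant!r}; choose from {sorted(VARIANT_SCALE)}"
        )
    model = model or CostModel()
    base = model.cost_overrides.get(float(dose_iu))
    if base is None:
        base = _parametric_base_cost(dose_iu, model)
    return round_half_up_int(base * VARIANT_SCALE[variant])


def savings(
    total_deaths: float, rrr: float, cost_per_death: float = DEFAULT_COST_PER_DEATH
) -> int:
    """Savings (thousand EUR) from prevented deaths at *rrr*.

    Computed on the unrounded prevented-death count, then rounded
    half-up to the nearest thousand EUR.
    """
    if total_deaths < 0 or cost_per_death < 0:
        raise DomainError("deaths and cost per death must be non-negative")
    if not 0 <= rrr <= 1:
        raise DomainError(f"RRR must lie in [0, 1], got {rrr}")
    return round_half_up_int(total_deaths * rrr * cost_per_death / 1000.0)


def net_savings(savings_keur: int, cost_keur: int) -> int:
    """Savings minus cost, in thousand EUR (integer arithmetic)."""
    return int(savings_keur) - int(cost_keur)


def cost_per_life_year(cost_keur: float, preventable_yll_value: float) -> int:
    """Cost per life-year saved (EUR), disregarding savings."""
    if cost_keur < 0:
        raise DomainError(f"cost must be non-negative, got {cost_keur}")
    if cost_keur == 0:
        return 0
    if preventable_yll_value <= 0:
        raise DomainError(
            f"preventable YLL must be positive, got {preventable_yll_value}"
        )
    return round_half_up_int(cost_keur * 1000.0 / preventable_yll_value)


def savings_cost_ratio(savings_keur: float, cost_keur: float) -> float:
    """Savings / cost at full precision."""
    if cost_keur <= 0:
        raise DomainError(f"cost must be positive, got {cost_keur}")
    return savings_keur / cost_keur
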