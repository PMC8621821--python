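"""Synthetic inputs with the statistical structure the pipeline assumes.

The real registry inputs (age/sex-stratified cancer deaths and a period
life table) are not redistributable, so this module generates stand-ins:
a unimodal age-at-death distribution over 5-year groups whose total is
conserved exactly, a linearly declining remaining-life-expectancy table,
and simulated study-effect sets for pooling recovery tests.

Default parameters are calibrated so the generated tables reproduce the
total-burden figures implied by the published scenario grid (total
deaths 229,827; total YLL ~2.79 million person-years) — calibration
targets, not registry values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .burden import GERMANY_2016_TOTAL_DEATHS, LifeTable, MortalityTable
from .errors import DomainError
from .meta_pool import StudyEffect

#: 5-year age groups 0-4 ... 80-84 plus the open-ended 85+ group.
AGE_GROUPS: tuple[tuple[int, int | None], ...] = tuple(
    (5 * i, 5 * i + 4) for i in range(17)
) + ((85, None),)

__all__ = [
    "AGE_GROUPS",
    "MortalityGenSpec",
    "StudyGenSpec",
    "largest_remainder",
    "gen_mortality_table",
    "gen_life_table",
    "gen_study_set",
    "default_burden_inputs",
]


@dataclass(frozen=True)
class MortalityGenSpec:
    """Parameters of the synthetic mortality-table generator.

    The age distribution is a discretized Gaussian over group midpoints
    with its mode in the 75-79 group; ``spread`` controls the shape.
    ``jitter`` adds seeded relative noise to the weights (0 disables it,
    keeping the generator fully deterministic).
    """

    total_deaths: int = GERMANY_2016_TOTAL_DEATHS
    mode_age: float = 78.0
    spread: float = 13.75
    sex_split_male: float = 0.54
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_deaths <= 0:
            raise DomainError(f"total deaths must be positive, got {self.total_deaths}")
        if self.spread <= 0:
            raise DomainError(f"spread must be positive, got {self.spread}")
        if not 0 <= self.sex_split_male <= 1:
            raise DomainError("sex split must lie in [0, 1]")
        if self.jitter < 0:
            raise DomainError("jitter must be non-negative")


@dataclass(frozen=True)
class StudyGenSpec:
    """Parameters of the simulated study-effect generator."""

    k: int = 20
    true_log_rr: float = -0.14
    tau2: float = 0.0
    se_range: tuple[float, float] = (0.05, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise DomainError(f"need k >= 2 studies, got {self.k}")
        if self.tau2 < 0:
            raise DomainError("tau2 must be non-negative")
        lo, hi = self.se_range
        if not (lo > 0 and hi >= lo):
            raise DomainError(f"invalid se range {self.se_range}")


def largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Allocate *total* integer units proportionally to *targets*.

    Floors each target and hands the leftover units to the cells with
    the largest fractional parts, so the result sums to *total* exactly.
    """
    targets = np.asarray(targets, dtype=float)
    if targets.sum() <= 0:
        raise DomainError("allocation targets must have positive sum")
    scaled = targets / targets.sum() * total
    floors = np.floor(scaled).astype(int)
    short = total - int(floors.sum())
    # ties broken by position for determinism
    order = np.argsort(-(scaled - floors), kind="stable")
    floors[order[:short]] += 1
    return floors


def _age_weights(spec: MortalityGenSpec, rng: np.random.Generator) -> np.ndarray:
    mids = np.array(
        [lo + 2.5 if hi is None else (lo + hi + 1) / 2 for lo, hi in AGE_GROUPS]
    )
    w = np.exp(-0.5 * ((mids - spec.mode_age) / spec.spread) ** 2)
    if spec.jitter > 0:
        w = w * rng.lognormal(mean=0.0, sigma=spec.jitter, size=w.size)
    return w / w.sum()


def gen_mortality_table(spec: MortalityGenSpec | None = None) -> MortalityTable:
    """Generate an age/sex mortality table conserving the total exactly."""
    spec = spec or MortalityGenSpec()
    rng = np.random.default_rng(spec.seed)
    w = _age_weights(spec, rng)
    targets = np.concatenate(
        [w * spec.sex_split_male, w * (1.0 - spec.sex_split_male)]
    )
    counts = largest_remainder(targets, spec.total_deaths)
    rows = []
    for j, sex in enumerate(("male", "female")):
        for i, (lo, hi) in enumerate(AGE_GROUPS):
            rows.append(
                {
                    "sex": sex,
                    "age_low": lo,
                    "age_high": float("nan") if hi is None else hi,
                    "deaths": int(counts[j * len(AGE_GROUPS) + i]),
                }
            )
    return MortalityTable(frame=pd.DataFrame(rows))


def gen_life_table(
    e0_male: float = 78.2,
    e0_female: float = 83.1,
    decline_rate: float = 0.94,
    floor: float = 1.5,
    max_age: int = 110,
    step: int = 5,
) -> LifeTable:
    """Linear remaining-life-expectancy table tabulated every *step* years.

    ex(age) = max(floor, e0 - decline_rate * age); decline_rate 0 yields
    a constant table. Female ex dominates male ex whenever
    e0_female >= e0_male.
    """
    if e0_male <= 0 or e0_female <= 0:
        raise DomainError("life expectancy at birth must be positive")
    if decline_rate < 0:
        raise DomainError("decline rate must be non-negative")
    if floor <= 0:
        raise DomainError("life-expectancy floor must be positive")
    ages = np.arange(0, max_age + 1, step)
    rows = []
    for sex, e0 in (("male", e0_male), ("female", e0_female)):
        ex = np.maximum(floor, e0 - decline_rate * ages)
        for a, e in zip(ages, ex):
            rows.append({"sex": sex, "age": float(a), "ex": float(e)})
    return LifeTable(frame=pd.DataFrame(rows))


def gen_study_set(spec: StudyGenSpec | None = None) -> list[StudyEffect]:
    """Simulate study effects: theta_i ~ N(true_log_rr, tau2), se_i ~ U."""
    spec = spec or StudyGenSpec()
    rng = np.random.default_rng(spec.seed)
    theta = rng.normal(spec.true_log_rr, math.sqrt(spec.tau2), size=spec.k)
    se = rng.uniform(spec.se_range[0], spec.se_range[1], size=spec.k)
    studies = []
    for i in range(spec.k):
        studies.append(
            StudyEffect(
                label=f"sim_{i + 1:03d}",
                rr=math.exp(theta[i]),
                ci_low=math.exp(theta[i] - 1.96 * se[i]),
                ci_high=math.exp(theta[i] + 1.96 * se[i]),
            )
        )
    return studies


def default_burden_inputs(seed: int = 0) -> tuple[MortalityTable, LifeTable]:
    """Calibrated default mortality + life tables for the worked example."""
    return (
        gen_mortality_table(MortalityGenSpec(seed=seed)),
        gen_life_table(),
    )
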