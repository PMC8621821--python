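"""Burden of disease: deaths, years of life lost, and preventable shares.

Years of life lost (YLL) are the age/sex-stratified death counts
weighted by remaining life expectancy at the midpoint of each 5-year
age group, summed over strata. Preventable burden scales total burden
by the scenario's relative risk reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._rounding import round_half_up_int
from .errors import CoverageError, DomainError

SEXES = ("male", "female")

#: Total cancer deaths in the Germany-2016 calibration. Back-solved from
#: the published scenario grid (25,281 prevented at an 11% reduction),
#: not itself a printed figure.
GERMANY_2016_TOTAL_DEATHS = 229_827

#: Effective years above the lower bound used as the open-ended top
#: group's midpoint (the source is silent on the convention).
DEFAULT_OPEN_GROUP_OFFSET = 2.5

__all__ = [
    "MortalityTable",
    "LifeTable",
    "BurdenSummary",
    "total_yll",
    "calibrate_total_deaths",
    "deaths_prevented",
    "preventable_yll",
    "group_midpoint",
    "GERMANY_2016_TOTAL_DEATHS",
]


def group_midpoint(
    age_low: float,
    age_high: float | None,
    open_group_offset: float = DEFAULT_OPEN_GROUP_OFFSET,
) -> float:
    """Midpoint of a 5-year age group; open-ended groups use an offset."""
    if age_high is None or (isinstance(age_high, float) and math.isnan(age_high)):
        return age_low + open_group_offset
    return (age_low + age_high + 1.0) / 2.0


@dataclass(frozen=True)
class MortalityTable:
    """Age/sex-stratified death counts.

    Backed by a DataFrame with columns sex, age_low, age_high (NaN for
    the open-ended top group) and deaths.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        required = {"sex", "age_low", "age_high", "deaths"}
        missing = required - set(df.columns)
        if missing:
            raise DomainError(f"mortality table missing columns: {sorted(missing)}")
        if (df["deaths"] < 0).any():
            raise DomainError("death counts must be non-negative")
        bad_sex = set(df["sex"]) - set(SEXES)
        if bad_sex:
            raise DomainError(f"unknown sex values: {sorted(bad_sex)}")
        for sex, sub in df.groupby("sex"):
            sub = sub.sort_values("age_low")
            n_open = sub["age_high"].isna().sum()
            if n_open > 1:
                raise DomainError(f"{sex}: more than one open-ended age group")
            if n_open == 1 and not math.isnan(sub["age_high"].iloc[-1]):
                raise DomainError(f"{sex}: open-ended group must be the last")
            closed = sub.dropna(subset=["age_high"])
            if (closed["age_high"] < closed["age_low"]).any():
                raise DomainError(f"{sex}: age_high below age_low")
            lows = sub["age_low"].to_numpy()
            highs = sub["age_high"].to_numpy()
            for i in range(len(sub) - 1):
                if math.isnan(highs[i]) or lows[i + 1] != highs[i] + 1:
                    raise DomainError(
                        f"{sex}: age groups must be contiguous and non-overlapping "
                        f"(gap after [{lows[i]}, {highs[i]}])"
                    )

    @property
    def total_deaths(self) -> float:
        return float(self.frame["deaths"].sum())

    def midpoints(
        self, open_group_offset: float = DEFAULT_OPEN_GROUP_OFFSET
    ) -> np.ndarray:
        return np.array(
            [
                group_midpoint(lo, hi, open_group_offset)
                for lo, hi in zip(self.frame["age_low"], self.frame["age_high"])
            ]
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "MortalityTable":
        df = pd.read_csv(path)
        df["age_high"] = pd.to_numeric(df["age_high"], errors="coerce")
        return cls(frame=df.reset_index(drop=True))

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out["age_high"] = out["age_high"].map(
            lambda v: "" if pd.isna(v) else int(v)
        )
        out.to_csv(path, index=False)


@dataclass(frozen=True)
class LifeTable:
    """Remaining life expectancy by sex and exact age.

    Lookups between tabulated ages are linearly interpolated; lookups
    outside the tabulated range raise :class:`CoverageError`.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        required = {"sex", "age", "ex"}
        missing = required - set(df.columns)
        if missing:
            raise DomainError(f"life table missing columns: {sorted(missing)}")
        if (df["ex"] <= 0).any():
            raise DomainError("remaining life expectancy must be positive")
        for sex, sub in df.groupby("sex"):
            ex = sub.sort_values("age")["ex"].to_numpy()
            if (np.diff(ex) > 1e-9).any():
                raise DomainError(
                    f"{sex}: remaining life expectancy must be non-increasing in age"
                )

    def lookup(self, sex: str, age: float) -> float:
        sub = self.frame[self.frame["sex"] == sex].sort_values("age")
        if sub.empty:
            raise CoverageError(f"life table has no rows for sex {sex!r}")
        ages = sub["age"].to_numpy(dtype=float)
        if not ages[0] <= age <= ages[-1]:
            raise CoverageError(
                f"age {age} for {sex} outside tabulated range "
                f"[{ages[0]}, {ages[-1]}]"
            )
        return float(np.interp(age, ages, sub["ex"].to_numpy(dtype=float)))

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        return cls(frame=pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass(frozen=True)
class BurdenSummary:
    """Totals over all strata of a mortality table."""

    total_deaths: float
    total_yll: float

    def __post_init__(self) -> None:
        if self.total_yll < 0:
            raise DomainError("total YLL cannot be negative")


def total_yll(
    deaths: MortalityTable,
    life: LifeTable,
    open_group_offset: float = DEFAULT_OPEN_GROUP_OFFSET,
) -> BurdenSummary:
    """Sum deaths x remaining life expectancy at group midpoints.

    Every (sex, midpoint) stratum must be resolvable in the life table;
    unresolvable strata are collected and reported together.
    """
    df = deaths.frame
    mids = deaths.midpoints(open_group_offset)
    yll = 0.0
    missing: list[str] = []
    for (_, row), mid in zip(df.iterrows(), mids):
        try:
            ex = life.lookup(row["sex"], mid)
        except CoverageError:
            missing.append(f"({row['sex']}, midpoint {mid})")
            continue
        yll += float(row["deaths"]) * ex
    if missing:
        raise CoverageError(
            "life table does not cover strata: " + ", ".join(missing)
        )
    return BurdenSummary(total_deaths=deaths.total_deaths, total_yll=yll)


def calibrate_total_deaths(prevented_at_anchor: float, rrr_anchor: float) -> int:
    """Back-solve the total death count from a (prevented, RRR) anchor."""
    if prevented_at_anchor <= 0:
        raise DomainError(
            f"prevented deaths must be positive, got {prevented_at_anchor}"
        )
    if not 0 < rrr_anchor < 1:
        raise DomainError(f"anchor RRR must be in (0, 1), got {rrr_anchor}")
    return round_half_up_int(prevented_at_anchor / rrr_anchor)


def deaths_prevented(total_deaths: float, rrr: float) -> float:
    """Unrounded prevented-death count total_deaths * rrr.

    Kept unrounded for downstream savings; round half-up for display.
    """
    if total_deaths < 0:
        raise DomainError(f"total deaths must be non-negative, got {total_deaths}")
    if not 0 <= rrr <= 1:
        raise DomainError(f"RRR must lie in [0, 1], got {rrr}")
    return total_deaths * rrr


def preventable_yll(total_yll_value: float, rrr: float) -> float:
    """Preventable YLL = total YLL x RRR (unrounded)."""
    if total_yll_value < 0:
        raise DomainError(f"total YLL must be non-negative, got {total_yll_value}")
    if not 0 <= rrr <= 1:
        raise DomainError(f"RRR must lie in [0, 1], got {rrr}")
    return total_yll_value * rrr
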