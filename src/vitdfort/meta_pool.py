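"""Inverse-variance random-effects pooling of study-level relative risks.

Implements the DerSimonian–Laird moment estimator with CI-derived
standard errors (the only per-study uncertainty printed in the evidence
tables), z-based confidence intervals, and leave-one-out sensitivity.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from ._rounding import round_half_up
from .errors import InsufficientStudiesError, InvalidStudyError, UnknownLabelError

Z_95 = 1.96

__all__ = [
    "StudyEffect",
    "LogEffect",
    "PooledEffect",
    "log_effect_from_ci",
    "dl_tau2",
    "pool_random_effects",
    "leave_one_out",
    "load_studies",
    "keum2019_studies",
]


@dataclass(frozen=True)
class StudyEffect:
    """One trial's relative risk with its 95% confidence interval.

    Metadata fields (country, dose, n) are carried through for reporting
    but play no role in the pooling arithmetic.
    """

    label: str
    rr: float
    ci_low: float
    ci_high: float
    country: str | None = None
    dose: str | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if not (self.rr > 0 and self.ci_low > 0 and self.ci_high > 0):
            raise InvalidStudyError(
                f"study {self.label!r}: rr and CI bounds must be strictly positive"
            )
        if not self.ci_low < self.ci_high:
            raise InvalidStudyError(
                f"study {self.label!r}: ci_low must be strictly below ci_high "
                f"(got {self.ci_low} >= {self.ci_high}); degenerate intervals are rejected"
            )
        if not (self.ci_low <= self.rr <= self.ci_high):
            raise InvalidStudyError(
                f"study {self.label!r}: rr {self.rr} outside CI "
                f"[{self.ci_low}, {self.ci_high}]"
            )


@dataclass(frozen=True)
class LogEffect:
    """Log-scale effect: theta = ln(RR) with its standard error."""

    theta: float
    se: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise InvalidStudyError(f"standard error must be positive, got {self.se}")


@dataclass(frozen=True)
class PooledEffect:
    """Random-effects pooled relative risk with heterogeneity diagnostics."""

    rr: float
    ci_low: float
    ci_high: float
    q: float
    tau2: float
    weights: dict[str, float] = field(default_factory=dict)
    theta: float = 0.0
    se: float = float("nan")

    def display(self) -> tuple[float, float, float]:
        """(rr, ci_low, ci_high) rounded half-up to 2 decimals for reporting."""
        return (
            round_half_up(self.rr, 2),
            round_half_up(self.ci_low, 2),
            round_half_up(self.ci_high, 2),
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        rr, lo, hi = self.display()
        return f"{rr:.2f} ({lo:.2f}–{hi:.2f})"


def log_effect_from_ci(study: StudyEffect, z: float = Z_95) -> LogEffect:
    """Convert a RR (95% CI) triple to a log-scale effect and SE.

    se = (ln(ci_high) - ln(ci_low)) / (2 z).
    """
    if z <= 0:
        raise InvalidStudyError(f"z must be positive, got {z}")
    theta = math.log(study.rr)
    se = (math.log(study.ci_high) - math.log(study.ci_low)) / (2.0 * z)
    if not se > 0:
        raise InvalidStudyError(
            f"study {study.label!r}: derived se is non-positive"
        )
    return LogEffect(theta=theta, se=se)


def dl_tau2(effects: Sequence[LogEffect]) -> tuple[float, float]:
    """DerSimonian–Laird moment estimate of between-study variance.

    Returns ``(q, tau2)`` where Q is Cochran's heterogeneity statistic
    under fixed-effect weights and tau2 is truncated at zero.
    """
    k = len(effects)
    if k < 2:
        raise InsufficientStudiesError(
            f"heterogeneity estimation needs at least 2 studies, got {k}"
        )
    theta = np.array([e.theta for e in effects])
    w = 1.0 / np.array([e.se for e in effects]) ** 2
    theta_fe = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - theta_fe) ** 2))
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    return q, tau2


def pool_random_effects(
    studies: Sequence[StudyEffect], z: float = Z_95
) -> PooledEffect:
    """Pool study relative risks with DL random-effects weights.

    Weights 1/(se_i^2 + tau2) on the log scale; CI uses the normal
    quantile *z* (no small-sample adjustment).
    """
    if len(studies) < 2:
        raise InsufficientStudiesError(
            f"pooling needs at least 2 studies, got {len(studies)}"
        )
    effects = [log_effect_from_ci(s, z=z) for s in studies]
    q, tau2 = dl_tau2(effects)
    w_star = np.array([1.0 / (e.se**2 + tau2) for e in effects])
    theta = np.array([e.theta for e in effects])
    theta_hat = float(np.sum(w_star * theta) / np.sum(w_star))
    se_pooled = float(1.0 / math.sqrt(np.sum(w_star)))
    norm_w = w_star / np.sum(w_star)
    return PooledEffect(
        rr=math.exp(theta_hat),
        ci_low=math.exp(theta_hat - z * se_pooled),
        ci_high=math.exp(theta_hat + z * se_pooled),
        q=q,
        tau2=tau2,
        weights={s.label: float(w) for s, w in zip(studies, norm_w)},
        theta=theta_hat,
        se=se_pooled,
    )


def leave_one_out(
    studies: Sequence[StudyEffect], excluded_label: str, z: float = Z_95
) -> PooledEffect:
    """Re-pool after removing the study with *excluded_label*."""
    if len(studies) < 3:
        raise InsufficientStudiesError(
            "leave-one-out needs at least 3 studies before exclusion, "
            f"got {len(studies)}"
        )
    labels = [s.label for s in studies]
    if excluded_label not in labels:
        raise UnknownLabelError(
            f"label {excluded_label!r} not among {labels}"
        )
    remaining = [s for s in studies if s.label != excluded_label]
    return pool_random_effects(remaining, z=z)


def load_studies(path: str | Path) -> list[StudyEffect]:
    """Read a study-effect CSV with header label,rr,ci_low,ci_high[,...]."""
    out: list[StudyEffect] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                StudyEffect(
                    label=row["label"],
                    rr=float(row["rr"]),
                    ci_low=float(row["ci_low"]),
                    ci_high=float(row["ci_high"]),
                    country=row.get("country") or None,
                    dose=row.get("dose") or None,
                    n=int(row["n"]) if row.get("n") else None,
                )
            )
    return out


def keum2019_studies() -> list[StudyEffect]:
    """The five daily/bolus supplementation RCTs of the cancer-mortality
    evidence base, as packaged fixture data."""
    ref = resources.files("vitdfort.data").joinpath("keum2019_studies.csv")
    with resources.as_file(ref) as path:
        return load_studies(path)
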