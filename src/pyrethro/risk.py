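"""Margins of exposure: external (MOE) and internal (MOIE) with uncertainty.

MOE divides the benchmark dose lower bound (BMDL, mg/kg) by the estimated
human daily intake (mg/kg/day); MOIE divides a systemic point-of-departure
dose metric — Cmax or AUC in plasma or brain simulated at the BMDL dose in
the rat model — by the corresponding predicted human dose metric.  Larger
margins mean lower risk; a margin distribution passes when its 5th
percentile meets the target (default 100 from 10 x 10 uncertainty
factors; a stricter target such as 1e4 is configurable).

Exposure can enter as a fixed summary (GM, P95, or P99 of the population
intake distribution — the top-percentile convention is a conservative
switch) or as a vector of Monte Carlo draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from pyrethro.errors import ConfigurationError, DomainError, ValidationError
from pyrethro.pbk import DoseMetrics

METRICS = ("cmax_plasma", "auc_plasma", "cmax_brain", "auc_brain")

ExposureSummary = Literal["gm", "p95", "p99"]


@dataclass(frozen=True)
class PodSet:
    """Point of departure: external BMDL and the systemic metrics at that dose."""

    compound: str
    bmdl: float  # mg/kg
    systemic: DoseMetrics

    def __post_init__(self) -> None:
        if not self.bmdl > 0:
            raise ValidationError("BMDL must be > 0")
        if any(self.systemic.metric(m) <= 0 for m in METRICS):
            raise ValidationError("systemic POD metrics must be > 0")


@dataclass(frozen=True)
class ExposureEstimate:
    """Population intake summary and human dose-metric draws for one compound."""

    compound: str
    intake_gm: float  # mg/kg/day
    intake_gsd: float
    metric_draws: Sequence[DoseMetrics] = ()

    def __post_init__(self) -> None:
        if not self.intake_gm > 0:
            raise ValidationError("intake GM must be > 0")
        if self.intake_gsd < 1:
            raise ValidationError("intake GSD must be >= 1")

    def intake_summary(self, which: ExposureSummary = "gm") -> float:
        z = {"gm": 0.0, "p95": 1.6449, "p99": 2.3263}[which]
        return self.intake_gm * self.intake_gsd**z

    def intake_draws(self, n: int, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        return self.intake_gm * np.exp(rng.standard_normal(n) * math.log(self.intake_gsd))


@dataclass(frozen=True)
class MarginResult:
    """A margin distribution with its summaries and acceptability flag."""

    compound: str
    kind: Literal["moe", "moie"]
    metric: str | None
    draws: np.ndarray
    target: float

    def __post_init__(self) -> None:
        if (np.asarray(self.draws) <= 0).any():
            raise ValidationError("margins must be > 0")

    @property
    def median(self) -> float:
        return float(np.median(self.draws))

    @property
    def p05(self) -> float:
        return float(np.percentile(self.draws, 5))

    @property
    def acceptable(self) -> bool:
        return self.p05 >= self.target

    def summary(self) -> dict:
        return {
            "compound": self.compound,
            "kind": self.kind,
            "metric": self.metric,
            "median": self.median,
            "p05": self.p05,
            "target": self.target,
            "acceptable": self.acceptable,
        }


def compute_moe(
    bmdl: float,
    exposure: float | np.ndarray | Sequence[float],
    target: float = 100.0,
    compound: str = "",
) -> MarginResult:
    """External margin: BMDL divided by the intake, element-wise over draws."""
    if bmdl <= 0:
        raise DomainError("BMDL must be > 0")
    exp_arr = np.atleast_1d(np.asarray(exposure, dtype=float))
    if (exp_arr <= 0).any():
        raise DomainError("exposure must be > 0")
    return MarginResult(compound=compound, kind="moe", metric=None, draws=bmdl / exp_arr, target=target)


def compute_moie(
    pod: PodSet,
    exposure: ExposureEstimate,
    metric: str,
    target: float = 100.0,
) -> MarginResult:
    """Internal margin: systemic POD metric over the human dose-metric draws."""
    if metric not in METRICS:
        raise ConfigurationError(f"unknown dose metric {metric!r}; choose from {METRICS}")
    if pod.compound != exposure.compound:
        raise ConfigurationError(
            f"POD is for {pod.compound!r} but exposure is for {exposure.compound!r}"
        )
    if not exposure.metric_draws:
        raise ConfigurationError("exposure carries no human dose-metric draws")
    human = np.array([dm.metric(metric) for dm in exposure.metric_draws])
    if (human <= 0).any():
        raise DomainError("human dose metrics must be > 0")
    return MarginResult(
        compound=pod.compound,
        kind="moie",
        metric=metric,
        draws=pod.systemic.metric(metric) / human,
        target=target,
    )


def margin_table(results: Sequence[MarginResult]) -> list[dict]:
    """Flat risk table (compound x kind x metric -> median, P05, flag)."""
    return [r.summary() for r in results]
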