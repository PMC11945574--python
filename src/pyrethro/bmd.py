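"""Bayesian benchmark-dose estimation for continuous endpoints with model averaging.

Dose-response data arrive as group summaries (dose, n, mean, SD) of a
continuous endpoint (locomotor activity).  Eight standard continuous
families — linear, power, 2nd-order polynomial, Hill, and exponential
models 2-5 — are fitted by MCMC with weakly-informative, data-scaled
priors, using the normal sufficient-statistics likelihood

    ll = sum_g [ -n_g ln(sigma) - ((n_g-1) s_g^2 + n_g (ybar_g - f(d_g))^2) / (2 sigma^2) ]

The benchmark response is a shift in the mean equal to one control SD
(the residual sigma), in the adverse direction — decreasing activity.  The
BMD solves f(0) - f(BMD) = sigma per posterior draw; draws with no
crossing below ten times the top dose are recorded as unbounded.

Posterior model weights come from Gelfand-Dey marginal-likelihood
estimates (a stabilized harmonic mean: an importance-weighted average with
a multivariate-normal weighting density fitted to the posterior draws).
The averaged BMD posterior is the weight-resampled mixture; BMD is its
median and BMDL its 5th percentile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from pyrethro._mcmc import adaptive_metropolis, split_rhat
from pyrethro.errors import ConvergenceError, DomainError, ValidationError

FAMILIES = ("linear", "power", "poly2", "hill", "exp2", "exp3", "exp4", "exp5")


@dataclass(frozen=True)
class DoseResponseData:
    """Group summaries of a continuous endpoint."""

    doses: np.ndarray  # mg/kg
    ns: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    endpoint: str = "locomotor activity"

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "ns", np.asarray(self.ns, dtype=float))
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))
        if len(np.unique(d)) != d.size or (d < 0).any():
            raise ValidationError("doses must be distinct and >= 0")
        if 0.0 not in d:
            raise ValidationError("a dose-0 control group is required")
        if (self.ns < 1).any() or (self.sds < 0).any():
            raise ValidationError("need n >= 1 and SD >= 0 in every group")

    @classmethod
    def from_csv(cls, path: str | Path, endpoint: str = "locomotor activity") -> "DoseResponseData":
        df = pd.read_csv(path)
        return cls(df["dose"].values, df["n"].values, df["mean"].values, df["sd"].values, endpoint)

    @property
    def control_mean(self) -> float:
        return float(self.means[np.argmin(self.doses)])

    @property
    def pooled_sd(self) -> float:
        w = self.ns - 1
        if w.sum() <= 0:
            return float(self.sds.mean())
        return float(np.sqrt(np.sum(w * self.sds**2) / w.sum()))


@dataclass(frozen=True)
class BmdModelSpec:
    """One family from the fixed continuous-model menu."""

    family: str
    prior_config: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}; menu is {FAMILIES}")


# --- mean functions --------------------------------------------------------
# theta excludes log_sigma (always the last coordinate of the sampled vector)

def _mean_linear(t: np.ndarray, d: np.ndarray) -> np.ndarray:
    return t[0] + t[1] * d


def _mean_power(t: np.ndarray, d: np.ndarray) -> np.ndarray:
    g = np.exp(t[2])
    return t[0] + t[1] * np.power(d, g)


def _mean_poly2(t: np.ndarray, d: np.ndarray) -> np.ndarray:
    return t[0] + t[1] * d + t[2] * d * d


def _mean_hill(t: np.ndarray, d: np.ndarray) -> np.ndarray:
    c, g = np.exp(t[2]), np.exp(t[3])
    dg = np.power(d, g)
    return t[0] + t[1] * dg / (c**g + dg)


def _mean_exp2(t: np.ndarray, d: np.ndarray) -> np.ndarray:
    return np.exp(t[0]) * np.exp(t[1] * d)


def _mean_exp3(t: np.ndarray, d: np.ndarray) -> np.ndarray:
    b, g = np.exp(t[1]), np.exp(t[2])
    return np.exp(t[0]) * np.exp(-np.power(b * d, g))


def _mean_exp4(t: np.ndarray, d: np.ndarray) -> np.ndarray:
    a, b = np.exp(t[0]), np.exp(t[1])
    c = 1.0 / (1.0 + np.exp(-t[2]))  # asymptote fraction in (0, 1): decreasing
    return a * (c + (1 - c) * np.exp(-b * d))


def _mean_exp5(t: np.ndarray, d: np.ndarray) -> np.ndarray:
    a, b = np.exp(t[0]), np.exp(t[1])
    c = 1.0 / (1.0 + np.exp(-t[2]))
    g = np.exp(t[3])
    return a * (c + (1 - c) * np.exp(-np.power(b * d, g)))


_MEANS: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "linear": _mean_linear,
    "power": _mean_power,
    "poly2": _mean_poly2,
    "hill": _mean_hill,
    "exp2": _mean_exp2,
    "exp3": _mean_exp3,
    "exp4": _mean_exp4,
    "exp5": _mean_exp5,
}
_NPAR = {"linear": 2, "power": 3, "poly2": 3, "hill": 4, "exp2": 2, "exp3": 3, "exp4": 3, "exp5": 4}


def _prior_scales(data: DoseResponseData) -> dict[str, float]:
    dmax = float(data.doses.max())
    span = float(np.ptp(data.means)) or data.pooled_sd or 1.0
    # unit-information scaling: priors carry roughly one observation's worth
    # of information at the data's own scale, so marginal likelihoods (and
    # hence model weights) are not dominated by arbitrary prior diffuseness
    return {
        "loc": data.control_mean,
        "loc_sd": abs(data.control_mean) + 2 * span,
        "slope_sd": 2 * span / max(dmax, 1e-12),
        "dmax": dmax,
        "log_sigma_loc": math.log(max(data.pooled_sd, 1e-6)),
    }


def _log_prior(family: str, theta: np.ndarray, sc: Mapping[str, float]) -> float:
    """Weakly-informative data-scaled priors; shape exponents lognormal near 1."""

    def n(x: float, loc: float, sd: float) -> float:
        return -0.5 * ((x - loc) / sd) ** 2 - math.log(sd)

    lp = n(theta[-1], sc["log_sigma_loc"], 1.5)  # log sigma
    t = theta[:-1]
    if family == "linear":
        lp += n(t[0], sc["loc"], sc["loc_sd"]) + n(t[1], 0, sc["slope_sd"])
    elif family == "power":
        lp += n(t[0], sc["loc"], sc["loc_sd"]) + n(t[1], 0, sc["slope_sd"]) + n(t[2], 0, 0.5)
    elif family == "poly2":
        lp += (
            n(t[0], sc["loc"], sc["loc_sd"])
            + n(t[1], 0, sc["slope_sd"])
            + n(t[2], 0, sc["slope_sd"] / max(sc["dmax"], 1e-12))
        )
    elif family == "hill":
        lp += (
            n(t[0], sc["loc"], sc["loc_sd"])
            + n(t[1], 0, sc["loc_sd"])
            + n(t[2], math.log(max(sc["dmax"], 1e-6) / 2), 1.5)
            + n(t[3], 0, 0.5)
        )
    elif family == "exp2":
        lp += n(t[0], math.log(abs(sc["loc"]) + 1e-6), 1.0) + n(t[1], 0, sc["slope_sd"] / (abs(sc["loc"]) + 1e-6))
    elif family == "exp3":
        lp += (
            n(t[0], math.log(abs(sc["loc"]) + 1e-6), 1.0)
            + n(t[1], -math.log(max(sc["dmax"], 1e-6)), 1.5)
            + n(t[2], 0, 0.5)
        )
    elif family in ("exp4", "exp5"):
        lp += (
            n(t[0], math.log(abs(sc["loc"]) + 1e-6), 1.0)
            + n(t[1], -math.log(max(sc["dmax"], 1e-6)), 1.5)
            + n(t[2], 0, 2.0)
        )
        if family == "exp5":
            lp += n(t[3], 0, 0.5)
    return lp


def _init_theta(family: str, data: DoseResponseData) -> np.ndarray:
    y0 = data.control_mean
    dmax = max(float(data.doses.max()), 1e-6)
    span = float(data.means.min() - y0)  # negative when decreasing
    slope = span / dmax
    log_a = math.log(abs(y0) + 1e-6)
    inits = {
        "linear": [y0, slope],
        "power": [y0, slope, 0.0],
        "poly2": [y0, slope, 0.0],
        "hill": [y0, span, math.log(dmax / 2), 0.0],
        "exp2": [log_a, slope / (abs(y0) + 1e-6)],
        "exp3": [log_a, -math.log(dmax), 0.0],
        "exp4": [log_a, -math.log(dmax), 0.0],
        "exp5": [log_a, -math.log(dmax), 0.0, 0.0],
    }
    theta = inits[family] + [math.log(max(data.pooled_sd, 1e-6))]
    return np.asarray(theta, dtype=float)


def _log_likelihood(family: str, theta: np.ndarray, data: DoseResponseData) -> float:
    sigma = math.exp(theta[-1])
    with np.errstate(over="ignore", invalid="ignore"):
        f = _MEANS[family](theta[:-1], data.doses)
    if not np.all(np.isfinite(f)):
        return -np.inf
    ss = (data.ns - 1) * data.sds**2 + data.ns * (data.means - f) ** 2
    return float(-np.sum(data.ns) * math.log(sigma) - np.sum(ss) / (2 * sigma**2))


def _bmd_from_draw(family: str, theta: np.ndarray, sigma: float, dmax: float) -> float:
    """Dose shifting the mean down by one control SD; inf when unbounded."""
    mean = _MEANS[family]

    def drop(d: float) -> float:
        return float(mean(theta, np.array([0.0]))[0] - mean(theta, np.array([d]))[0]) - sigma

    hi = 10.0 * dmax
    if not np.isfinite(drop(hi)) or drop(hi) < 0:
        return np.inf
    try:
        return float(brentq(drop, 0.0, hi, xtol=1e-10 * max(dmax, 1.0)))
    except ValueError:
        return np.inf


@dataclass
class BmdFit:
    """Posterior of one dose-response family."""

    family: str
    bmd_draws: np.ndarray  # pooled over chains; may contain inf
    theta_draws: np.ndarray  # (total kept, dim)
    log_marginal: float
    rhat: float
    converged: bool
    fraction_unbounded: float
    acceptance: float


@dataclass(frozen=True)
class AveragedBmd:
    """Model-averaged BMD posterior and its summaries."""

    bmd: float  # posterior median, mg/kg
    bmdl: float  # lower percentile of the mixture
    bmdu: float  # matching upper percentile
    weights: Mapping[str, float]
    draws: np.ndarray
    lower_percentile: float = 5.0

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.weights.values()), 1.0, abs_tol=1e-9):
            raise ValidationError("weights must sum to 1")
        if any(w < 0 for w in self.weights.values()):
            raise ValidationError("weights must be >= 0")
        if self.bmdl > self.bmd + 1e-12:
            raise ValidationError("BMDL must not exceed BMD")


def fit_bmd_model(
    data: DoseResponseData,
    model: BmdModelSpec | str,
    chains: int = 3,
    iterations: int = 30000,
    seed: int = 0,
    bmr_sd: float = 1.0,
) -> BmdFit:
    """MCMC fit of one family; the last half of each chain is kept.

    The BMD is computed per kept draw at a benchmark response of ``bmr_sd``
    control standard deviations below the control mean.
    """
    if isinstance(model, str):
        model = BmdModelSpec(model)
    family = model.family
    sc = _prior_scales(data)
    dim = _NPAR[family] + 1

    def log_post(theta: np.ndarray) -> float:
        lp = _log_prior(family, theta, sc)
        if not np.isfinite(lp):
            return -np.inf
        return lp + _log_likelihood(family, theta, data)

    master = np.random.SeedSequence([seed, FAMILIES.index(family)])
    keep = iterations // 2
    kept_list, rates = [], []
    for child in master.spawn(chains):
        rng = np.random.default_rng(child)
        x0 = _init_theta(family, data) + 0.05 * rng.standard_normal(dim)
        chain, rate = adaptive_metropolis(log_post, x0, iterations, rng, initial_scale=0.05)
        kept_list.append(chain[-keep:])
        rates.append(rate)

    kept = np.stack(kept_list)  # (chains, keep, dim)
    rh = max(split_rhat(kept[:, :, j]) for j in range(dim))
    converged = rh < 1.1

    theta_all = kept.reshape(-1, dim)
    dmax = float(data.doses.max())
    bmd_draws = np.array(
        [
            _bmd_from_draw(family, t[:-1], bmr_sd * math.exp(t[-1]), dmax)
            for t in theta_all
        ]
    )
    log_marg = _gelfand_dey(theta_all, family, data, sc)
    return BmdFit(
        family=family,
        bmd_draws=bmd_draws,
        theta_draws=theta_all,
        log_marginal=log_marg,
        rhat=rh,
        converged=converged,
        fraction_unbounded=float(np.mean(~np.isfinite(bmd_draws))),
        acceptance=float(np.mean(rates)),
    )


def _gelfand_dey(theta: np.ndarray, family: str, data: DoseResponseData, sc: Mapping[str, float]) -> float:
    """Gelfand-Dey marginal likelihood from posterior draws.

    1/m = E_post[ h(theta) / (prior x likelihood) ] with h a multivariate
    normal matched to the posterior draws — the stabilized harmonic mean.
    """
    sub = theta[:: max(1, len(theta) // 2000)]
    mean = sub.mean(axis=0)
    cov = np.cov(sub.T).reshape(len(mean), len(mean)) + 1e-10 * np.eye(len(mean))
    inv = np.linalg.inv(cov)
    _, logdet = np.linalg.slogdet(cov)
    d = len(mean)
    diffs = sub - mean
    maha = np.einsum("ij,jk,ik->i", diffs, inv, diffs)
    log_h = -0.5 * (d * math.log(2 * math.pi) + logdet + maha)
    log_pl = np.array(
        [_log_prior(family, t, sc) + _log_likelihood(family, t, data) for t in sub]
    )
    ratios = log_h - log_pl
    # 1/m = mean(exp(ratios)); stabilize with log-sum-exp
    mx = np.max(ratios)
    log_inv_m = mx + math.log(np.mean(np.exp(ratios - mx)))
    return -float(log_inv_m)


def posterior_model_weights(fits: Sequence[BmdFit]) -> dict[str, float]:
    """Normalized posterior model weights over the converged fits."""
    usable = [f for f in fits if f.converged]
    skipped = [f.family for f in fits if not f.converged]
    if skipped:
        warnings.warn(f"excluding non-converged families from averaging: {skipped}")
    if not usable:
        raise ConvergenceError("no converged dose-response fit available")
    logs = np.array([f.log_marginal for f in usable])
    logs -= logs.max()
    w = np.exp(logs)
    w /= w.sum()
    return {f.family: float(wi) for f, wi in zip(usable, w)}


def model_average_bmd(
    fits: Sequence[BmdFit],
    weights: Mapping[str, float] | None = None,
    lower_percentile: float = 5.0,
    n_mixture: int = 20000,
    seed: int = 0,
) -> AveragedBmd:
    """Weight-resampled mixture of the per-model BMD posteriors."""
    if weights is None:
        weights = posterior_model_weights(fits)
    by_family = {f.family: f for f in fits}
    rng = np.random.default_rng(seed)
    fams = [f for f in weights if weights[f] > 0]
    probs = np.array([weights[f] for f in fams])
    probs = probs / probs.sum()
    counts = rng.multinomial(n_mixture, probs)
    parts = []
    for fam, cnt in zip(fams, counts):
        if cnt == 0:
            continue
        draws = by_family[fam].bmd_draws
        parts.append(rng.choice(draws, size=cnt, replace=True))
    mixture = np.concatenate(parts)
    finite = mixture[np.isfinite(mixture)]
    if finite.size == 0:
        raise DomainError("averaged BMD posterior is entirely unbounded (no dose effect)")
    bmd = float(np.median(mixture)) if np.isfinite(np.median(mixture)) else float("inf")
    return AveragedBmd(
        bmd=bmd,
        bmdl=float(np.percentile(mixture, lower_percentile)),
        bmdu=float(np.percentile(finite, 100 - lower_percentile)),
        weights={f.family: float(weights.get(f.family, 0.0)) for f in fits},
        draws=mixture,
        lower_percentile=lower_percentile,
    )


def report(fits: Sequence[BmdFit], averaged: AveragedBmd) -> dict:
    """JSON-ready summary: per-model weights, diagnostics, averaged BMD/BMDL."""
    return {
        "models": [
            {
                "family": f.family,
                "weight": averaged.weights.get(f.family, 0.0),
                "bmd_median": float(np.median(f.bmd_draws)),
                "rhat": f.rhat,
                "converged": f.converged,
                "fraction_unbounded": f.fraction_unbounded,
                "log_marginal": f.log_marginal,
            }
            for f in fits
        ],
        "bmd": averaged.bmd,
        "bmdl": averaged.bmdl,
        "bmdu": averaged.bmdu,
        "lower_percentile": averaged.lower_percentile,
    }
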