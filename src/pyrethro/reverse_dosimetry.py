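"""Bayesian reconstruction of pyrethroid intakes from censored urine surveys.

The population model, per survey stratum (age group x cycle):

* each individual i carries a latent daily intake ``exp(u_gi)`` (mg/kg/day)
  of each free parent group g, with ``u_gi ~ Normal(mu_g, sigma2_g)``;
* the steady-state PBK map converts intakes to predicted metabolite
  concentrations, linear in each intake with a per-individual coefficient
  built from body weight, absorbed fraction, molar transformation fractions
  and urine output;
* detected observations are lognormal around the prediction with residual
  variance ``sigma2_res`` per metabolite; non-detects contribute a normal
  density with standard deviation LOD/4 evaluated at a policy value (0 or
  LOD/2) against the prediction.

Priors: population median intake uniform on log10 over [-12, 0] mg/kg/day;
population variance inverse-gamma(shape 5, scale 2.25) (prior mean 0.5625,
i.e. a GSD near 2); residual variance half-normal with scale 0.3 (GSD near
1.7).  Sampling is Metropolis-within-Gibbs: vectorized single-site
Metropolis for the latent intakes, conjugate (truncated-normal /
inverse-gamma) Gibbs draws for the population mean and variance, and a
scalar Metropolis step on each log residual variance.

Isomers of a parent group share the group intake through fixed isomer
fractions; cypermethrin, which lacks a specific biomarker, is tied to
permethrin by a fixed intake ratio.

The module also implements the simplified high-throughput comparator:
a censored-lognormal fit of the urine concentrations followed by a direct
steady-state inversion to a parent intake.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from pyrethro._mcmc import split_rhat
from pyrethro.chem_map import CYPERMETHRIN_PERMETHRIN_RATIO, Registry
from pyrethro.errors import ConfigurationError, DomainError, ValidationError
from pyrethro.pbk import MG_PER_L_TO_NG_PER_ML, PbkParameters, Physiology
from pyrethro.survey_data import SurveyTable

LodPolicy = Literal["zero", "half_lod"]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class PriorSpec:
    """Priors of the population intake model."""

    log10_intake_low: float = -12.0
    log10_intake_high: float = 0.0
    pop_var_shape: float = 5.0
    pop_var_scale: float = 2.25
    residual_scale: float = 0.3

    def __post_init__(self) -> None:
        if not self.log10_intake_low < self.log10_intake_high:
            raise ValidationError("intake prior interval must have lower < upper")
        if not self.pop_var_shape > 2:
            raise ValidationError("inverse-gamma shape must be > 2 (finite prior variance)")
        if self.pop_var_scale <= 0 or self.residual_scale <= 0:
            raise ValidationError("prior scales must be > 0")

    @property
    def prior_mean_pop_var(self) -> float:
        """Mean of the inverse-gamma prior on the population log-variance."""
        return self.pop_var_scale / (self.pop_var_shape - 1)

    @property
    def prior_mean_pop_gsd(self) -> float:
        """GSD implied by the prior-mean population variance: exp(sqrt(var))."""
        return math.exp(math.sqrt(self.prior_mean_pop_var))

    @property
    def residual_gsd(self) -> float:
        """GSD implied by a residual variance equal to the half-normal scale."""
        return math.exp(math.sqrt(self.residual_scale))


@dataclass(frozen=True)
class ConvergenceReport:
    """Split-R-hat and effective sample size per monitored parameter."""

    rhat: Mapping[str, float]
    ess: Mapping[str, float]
    threshold: float = 1.1

    @property
    def passed(self) -> bool:
        return all(r < self.threshold for r in self.rhat.values())


@dataclass
class PosteriorDraws:
    """Kept MCMC draws: population parameters, plus latent-intake summaries.

    ``draws`` maps parameter name -> array of shape (chains, kept
    iterations).  Latent individual intakes are summarized by their
    per-iteration mean (full storage would dwarf the population draws).
    """

    draws: dict[str, np.ndarray]
    seed: int
    acceptance: dict[str, float] = field(default_factory=dict)

    def convergence(self) -> ConvergenceReport:
        return gelman_rubin(self.draws)

    def summary(self) -> pd.DataFrame:
        """Posterior medians, credible intervals, and GM/GSD where applicable."""
        rows = []
        for name, arr in self.draws.items():
            flat = arr.reshape(-1)
            row = {
                "parameter": name,
                "median": float(np.median(flat)),
                "ci5": float(np.percentile(flat, 5)),
                "ci95": float(np.percentile(flat, 95)),
            }
            if name.startswith("log10_intake["):
                row["gm_intake"] = float(10 ** np.median(flat))
            if name.startswith("pop_var[") or name.startswith("res_var["):
                row["gsd"] = float(np.exp(np.sqrt(np.median(flat))))
            rows.append(row)
        return pd.DataFrame(rows)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (chain, iteration, parameter, value) draw table."""
        records = []
        for name, arr in self.draws.items():
            n_chain, n_iter = arr.shape
            for c in range(n_chain):
                records.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iteration": np.arange(n_iter),
                            "parameter": name,
                            "value": arr[c],
                        }
                    )
                )
        return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def log_likelihood(
    observed: float | None,
    below_lod: bool,
    lod: float,
    predicted_concentration: float,
    residual_sd: float,
    lod_policy: LodPolicy = "half_lod",
) -> float:
    """Log density of one record given the model prediction.

    Detected records are lognormal around the prediction (log-scale sd
    ``residual_sd``); non-detects contribute a normal density with sd LOD/4
    evaluated at the policy value (0 or LOD/2) against the prediction.
    """
    if predicted_concentration <= 0:
        raise DomainError("predicted concentration must be > 0")
    if below_lod:
        value = 0.0 if lod_policy == "zero" else lod / 2.0
        return float(norm.logpdf(value, loc=predicted_concentration, scale=lod / 4.0))
    if observed is None or observed <= 0:
        raise DomainError("detected record needs a positive observed value")
    z = (math.log(observed) - math.log(predicted_concentration)) / residual_sd
    return -math.log(observed * residual_sd * math.sqrt(2 * math.pi)) - 0.5 * z * z


# ---------------------------------------------------------------------------
# Full Bayesian sampler
# ---------------------------------------------------------------------------

def _stratum_design(
    df: pd.DataFrame,
    registry: Registry,
    params: Mapping[str, PbkParameters] | None,
    physiology: Physiology,
    free_groups: Sequence[str],
    derived_ratios: Mapping[str, tuple[str, float]],
) -> tuple[np.ndarray, list[str], dict[str, np.ndarray], np.ndarray, np.ndarray, np.ndarray]:
    """Arrange one stratum as individuals x metabolites arrays.

    Returns (body weights, metabolite list, per-group coefficient matrices K
    such that C = sum_g K_g * exp(u_g)[:, None], observed matrix, lod
    matrix, censoring mask).  Missing (individual, metabolite) entries are
    NaN in the observation matrix and masked out of both likelihood terms.
    """
    subjects = df["subject_id"].unique()
    mets = sorted(df["metabolite"].unique())
    n, m = len(subjects), len(mets)
    sub_idx = {s: i for i, s in enumerate(subjects)}
    met_idx = {mm: j for j, mm in enumerate(mets)}

    obs = np.full((n, m), np.nan)
    lod = np.full((n, m), np.nan)
    cens = np.zeros((n, m), dtype=bool)
    bw = np.full(n, physiology.body_weight)
    for row in df.itertuples():
        i, j = sub_idx[row.subject_id], met_idx[row.metabolite]
        lod[i, j] = row.lod
        if row.below_lod:
            cens[i, j] = True
        else:
            obs[i, j] = row.value
        if np.isfinite(row.body_weight):
            bw[i] = row.body_weight

    v_urine = physiology.daily_urine_volume
    k_by_group: dict[str, np.ndarray] = {}
    group_members: dict[str, list[str]] = {}
    for cid, spec in registry.compounds.items():
        group_members.setdefault(spec.parent_group, []).append(cid)

    def group_coeff(group: str, mid: str) -> float:
        total = 0.0
        for cid in group_members.get(group, []):
            spec = registry.compound(cid)
            f_abs = params[cid].f_abs if params is not None else 1.0
            total += spec.isomer_fraction * f_abs * registry.mass_yield(cid, mid)
        return total

    for g in free_groups:
        coeffs = np.zeros(m)
        for mid, j in met_idx.items():
            c = group_coeff(g, mid)
            for dgroup, (src, ratio) in derived_ratios.items():
                if src == g:
                    c += ratio * group_coeff(dgroup, mid)
            coeffs[j] = c
        # C [ng/mL] = intake [mg/kg/d] * BW / V_urine * coeff * 1000
        k_by_group[g] = np.outer(bw / v_urine, coeffs) * MG_PER_L_TO_NG_PER_ML
    return bw, mets, k_by_group, obs, lod, cens


def _data_loglik_per_individual(
    c_pred: np.ndarray,
    log_obs: np.ndarray,
    det_mask: np.ndarray,
    cens_mask: np.ndarray,
    policy_val: np.ndarray,
    lod_sd: np.ndarray,
    res_sd: np.ndarray,
) -> np.ndarray:
    """Sum of record log densities per individual (constants dropped)."""
    with np.errstate(divide="ignore"):
        logc = np.log(c_pred)
    det_term = np.where(
        det_mask, -0.5 * ((log_obs - logc) / res_sd) ** 2 - np.log(res_sd), 0.0
    )
    cens_term = np.where(cens_mask, -0.5 * ((policy_val - c_pred) / lod_sd) ** 2, 0.0)
    return det_term.sum(axis=1) + cens_term.sum(axis=1)


def sample_posterior(
    table: SurveyTable,
    registry: Registry,
    params: Mapping[str, PbkParameters] | None,
    physiology_by_age: Mapping[str, Physiology],
    priors: PriorSpec | None = None,
    chains: int = 3,
    iterations: int = 10000,
    burn_in: float = 0.5,
    seed: int = 0,
    lod_policy: LodPolicy = "half_lod",
    free_groups: Sequence[str] | None = None,
    derived_ratios: Mapping[str, tuple[str, float]] | None = None,
    latent_sweeps: int = 3,
) -> PosteriorDraws:
    """Draw from the joint posterior of population intake parameters.

    One independent hierarchical model is fitted per (age group, cycle)
    stratum; population medians are not shared across cycles.
    """
    priors = priors or PriorSpec()
    if derived_ratios is None:
        derived_ratios = (
            {"cypermethrin": ("permethrin", CYPERMETHRIN_PERMETHRIN_RATIO)}
            if any(registry.compound(c).parent_group == "cypermethrin" for c in registry.compounds)
            else {}
        )
    groups_in_registry = sorted({c.parent_group for c in registry.compounds.values()})
    if free_groups is None:
        free_groups = [g for g in groups_in_registry if g not in derived_ratios]

    # identifiability precondition: every measured metabolite present in the
    # table must map to at least one parent in the registry
    for mid in table.frame["metabolite"].unique():
        if not registry.parents_of(mid):
            raise ConfigurationError(f"metabolite {mid!r} has no parent pathway in the registry")

    lo, hi = priors.log10_intake_low * LN10, priors.log10_intake_high * LN10
    n_keep = iterations - int(burn_in * iterations)
    draws: dict[str, np.ndarray] = {}
    acceptance: dict[str, float] = {}

    strata = list(table.frame.groupby(["age_group", "cycle"], observed=True))
    master = np.random.SeedSequence(seed)
    for (age_group, cycle), df in strata:
        if age_group not in physiology_by_age:
            raise ConfigurationError(f"no physiology for age group {age_group!r}")
        phys = physiology_by_age[age_group]
        bw, mets, k_by_group, obs, lod, cens = _stratum_design(
            df, registry, params, phys, free_groups, derived_ratios
        )
        det = np.isfinite(obs)
        log_obs = np.where(det, np.log(np.where(det, obs, 1.0)), 0.0)
        policy_val = np.where(cens, 0.0 if lod_policy == "zero" else lod / 2.0, 0.0)
        lod_sd = np.where(cens, lod / 4.0, 1.0)
        n = bw.size
        active = [g for g in free_groups if k_by_group[g].max() > 0]

        tag = f"{age_group}|{cycle}"
        for g in active:
            draws[f"log10_intake[{g}|{tag}]"] = np.empty((chains, n_keep))
            draws[f"pop_var[{g}|{tag}]"] = np.empty((chains, n_keep))
        res_names = {}
        for j, mid in enumerate(mets):
            if det[:, j].any():
                res_names[j] = f"res_var[{mid}|{tag}]"
                draws[res_names[j]] = np.empty((chains, n_keep))

        # crude data-driven center for overdispersed chain starts
        mu_init = {}
        for g in active:
            kg = k_by_group[g]
            j_best = int(np.argmax(kg.mean(axis=0)))
            vals = obs[:, j_best]
            level = np.nanmedian(vals) if np.isfinite(vals).any() else lod[:, j_best].mean() / 2
            mu_init[g] = float(
                np.clip(np.log(max(level, 1e-12) / max(kg[:, j_best].mean(), 1e-300)), lo, hi)
            )

        for chain, child in enumerate(master.spawn(chains)):
            rng = np.random.default_rng(child)
            mu = {g: float(np.clip(mu_init[g] + rng.normal(0, 0.5), lo, hi)) for g in active}
            pop_var = {g: priors.prior_mean_pop_var for g in active}
            res_var = {j: priors.residual_scale for j in res_names}
            u = {g: mu[g] + rng.normal(0, math.sqrt(pop_var[g]), n) for g in active}
            step = {g: 0.5 for g in active}
            res_step = {j: 0.5 for j in res_names}
            n_burn = iterations - n_keep
            acc_count = {g: 0 for g in active}

            c_pred = np.zeros_like(obs, dtype=float)
            for g in active:
                c_pred += k_by_group[g] * np.exp(u[g])[:, None]

            res_sd_row = np.ones(len(mets))
            for j in res_names:
                res_sd_row[j] = math.sqrt(res_var[j])

            for it in range(iterations):
                # 1. latent intakes: vectorized single-site Metropolis per
                #    group.  Several sweeps per stored iteration shorten the
                #    autocorrelation of the residual sum of squares, which
                #    otherwise mixes slowly for compound-specific biomarkers
                #    whose latents chase a single record.
                ll_cur = _data_loglik_per_individual(
                    c_pred, log_obs, det, cens, policy_val, lod_sd, res_sd_row
                )
                for _sweep in range(latent_sweeps):
                    for g in active:
                        prop = u[g] + step[g] * rng.standard_normal(n)
                        inside = (prop >= lo) & (prop <= hi)
                        delta = k_by_group[g] * (np.exp(prop) - np.exp(u[g]))[:, None]
                        c_new = np.maximum(c_pred + delta, 1e-300)
                        ll_new = _data_loglik_per_individual(
                            c_new, log_obs, det, cens, policy_val, lod_sd, res_sd_row
                        )
                        lp_new = -0.5 * (prop - mu[g]) ** 2 / pop_var[g]
                        lp_old = -0.5 * (u[g] - mu[g]) ** 2 / pop_var[g]
                        accept = inside & (
                            np.log(rng.random(n)) < (ll_new + lp_new) - (ll_cur + lp_old)
                        )
                        u[g] = np.where(accept, prop, u[g])
                        c_pred = np.where(accept[:, None], c_new, c_pred)
                        ll_cur = np.where(accept, ll_new, ll_cur)
                        rate = accept.mean()
                        if it < n_burn:
                            step[g] *= math.exp((rate - 0.35) * 0.2)
                        else:
                            acc_count[g] += int(accept.sum())

                # 2. population mean: truncated-normal Gibbs
                for g in active:
                    m_bar = u[g].mean()
                    s = math.sqrt(pop_var[g] / n)
                    a, b = ndtr((lo - m_bar) / s), ndtr((hi - m_bar) / s)
                    p = a + (b - a) * rng.random()
                    mu[g] = m_bar + s * float(ndtri(min(max(p, 1e-15), 1 - 1e-15)))

                # 3. population variance: conjugate inverse-gamma Gibbs
                for g in active:
                    a_post = priors.pop_var_shape + n / 2
                    b_post = priors.pop_var_scale + 0.5 * float(np.sum((u[g] - mu[g]) ** 2))
                    pop_var[g] = 1.0 / rng.gamma(a_post, 1.0 / b_post)

                # 4. residual variances: scalar Metropolis on log variance,
                #    half-normal prior on the variance itself
                for j, name in res_names.items():
                    dj = det[:, j]
                    resid = log_obs[dj, j] - np.log(c_pred[dj, j])
                    n_det = int(dj.sum())
                    sq = float(np.sum(resid**2))

                    def lp(v: float) -> float:
                        return (
                            -0.5 * n_det * math.log(v)
                            - 0.5 * sq / v
                            - v**2 / (2 * priors.residual_scale**2)
                            + math.log(v)  # Jacobian of the log transform
                        )

                    # several sub-steps: the sufficient statistics are fixed,
                    # so extra proposals are nearly free and fix slow mixing
                    # of weakly-identified metabolites (few detects)
                    for _ in range(5):
                        v_cur = res_var[j]
                        v_prop = math.exp(math.log(v_cur) + res_step[j] * rng.standard_normal())
                        acc = math.log(rng.random()) < lp(v_prop) - lp(v_cur)
                        if acc:
                            res_var[j] = v_prop
                        if it < n_burn:
                            res_step[j] *= math.exp(((1.0 if acc else 0.0) - 0.35) * 0.25)
                    res_sd_row[j] = math.sqrt(res_var[j])

                if it >= n_burn:
                    k = it - n_burn
                    for g in active:
                        draws[f"log10_intake[{g}|{tag}]"][chain, k] = mu[g] / LN10
                        draws[f"pop_var[{g}|{tag}]"][chain, k] = pop_var[g]
                    for j, name in res_names.items():
                        draws[name][chain, k] = res_var[j]

            for g in active:
                acceptance[f"latent[{g}|{tag}]|chain{chain}"] = acc_count[g] / (
                    n_keep * n * latent_sweeps
                )

    return PosteriorDraws(draws=draws, seed=seed, acceptance=acceptance)


def gelman_rubin(chains: Mapping[str, np.ndarray], threshold: float = 1.1) -> ConvergenceReport:
    """Split-R-hat and a crude effective sample size per parameter.

    ``chains`` maps parameter name -> (n_chains, n_iterations) draw matrix.
    """
    rhat, ess = {}, {}
    for name, arr in chains.items():
        arr = np.asarray(arr, dtype=float)
        rhat[name] = split_rhat(arr)
        ess[name] = _effective_sample_size(arr)
    return ConvergenceReport(rhat=rhat, ess=ess, threshold=threshold)


def _effective_sample_size(arr: np.ndarray) -> float:
    """ESS from pooled autocorrelations (Geyer initial positive sequence)."""
    m, n = arr.shape
    if n < 4:
        return float(m * n)
    centered = arr - arr.mean(axis=1, keepdims=True)
    var = centered.var(axis=1).mean()
    if var == 0:
        return float(m * n)
    max_lag = min(n - 1, 1000)
    rho_sum = 0.0
    for lag in range(1, max_lag):
        rho = np.mean(
            [np.dot(centered[c, :-lag], centered[c, lag:]) / n for c in range(m)]
        ) / var
        if rho < 0.05:
            break
        rho_sum += rho
    return float(m * n / (1 + 2 * rho_sum))


# ---------------------------------------------------------------------------
# Simplified high-throughput comparator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CensoredLognormalFit:
    """Maximum-likelihood GM/GSD of a left-censored lognormal sample."""

    gm: float | None
    gsd: float | None
    n: int
    n_censored: int
    all_censored: bool
    upper_bound: float | None = None  # GM bound when everything is censored

    def cdf_report(self, probs: Sequence[float] = (0.25, 0.5, 0.75, 0.9, 0.95)) -> pd.DataFrame:
        """Fitted vs empirical-style quantiles for goodness-of-fit checks."""
        if self.all_censored:
            raise DomainError("no point estimate for an all-censored sample")
        q = [self.gm * self.gsd ** norm.ppf(p) for p in probs]
        return pd.DataFrame({"prob": probs, "fitted_quantile": q})


def censored_lognormal_fit(
    values: np.ndarray | Sequence[float],
    below_lod: np.ndarray | Sequence[bool],
    lods: np.ndarray | Sequence[float],
) -> CensoredLognormalFit:
    """Fit GM and GSD under left-censoring by maximum likelihood.

    Detected values contribute lognormal densities; censored records
    contribute the probability mass below their LOD.  With no censoring the
    estimator reduces exactly to the sample GM and e**sd(ln x).
    """
    values = np.asarray(values, dtype=float)
    cens = np.asarray(below_lod, dtype=bool)
    lods = np.asarray(lods, dtype=float)
    n = values.size
    det = ~cens
    if not det.any():
        return CensoredLognormalFit(
            gm=None, gsd=None, n=n, n_censored=int(cens.sum()), all_censored=True,
            upper_bound=float(np.exp(np.log(lods).mean())),
        )
    logs_det = np.log(values[det])
    log_lods = np.log(lods[cens]) if cens.any() else np.empty(0)

    if not cens.any():
        mu = logs_det.mean()
        sd = logs_det.std(ddof=1) if logs_det.size > 1 else 0.0
        return CensoredLognormalFit(float(np.exp(mu)), float(np.exp(sd)), n, 0, False)

    def nll(theta: np.ndarray) -> float:
        mu, log_sd = theta
        sd = math.exp(log_sd)
        ll = np.sum(norm.logpdf(logs_det, mu, sd))
        ll += np.sum(norm.logcdf((log_lods - mu) / sd))
        return -float(ll)

    x0 = np.array([logs_det.mean(), math.log(max(logs_det.std(ddof=0), 0.1))])
    res = minimize(nll, x0, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10})
    mu, sd = res.x[0], math.exp(res.x[1])
    return CensoredLognormalFit(
        gm=float(np.exp(mu)), gsd=float(np.exp(sd)), n=n, n_censored=int(cens.sum()),
        all_censored=False,
    )


def ht_intake_estimate(
    metabolite_gm: float,
    metabolite_id: str,
    registry: Registry,
    physiology: Physiology,
    attribution: Mapping[str, float] | None = None,
    params: Mapping[str, PbkParameters] | None = None,
) -> dict[str, float]:
    """Steady-state inversion of a metabolite GM to parent intake GMs.

    intake_p = GM_urine * V_urine * attribution_p / (BW * mass yield * f_abs).
    ``attribution`` apportions the metabolite across parents (defaults to the
    sole parent when unique).  Units: ng/mL in, mg/kg/day out.
    """
    if metabolite_gm < 0:
        raise DomainError("metabolite GM must be >= 0")
    parents = registry.parents_of(metabolite_id)
    if not parents:
        raise ConfigurationError(f"metabolite {metabolite_id!r} attributable to no parent")
    if attribution is None:
        if len(parents) > 1:
            raise ConfigurationError(
                f"{metabolite_id!r} has multiple parents; attribution fractions required"
            )
        attribution = {parents[0]: 1.0}
    out = {}
    for cid, frac in attribution.items():
        y = registry.mass_yield(cid, metabolite_id)
        if y <= 0:
            raise ConfigurationError(f"zero mass yield for {cid} -> {metabolite_id}")
        f_abs = params[cid].f_abs if params is not None else 1.0
        out[cid] = (
            metabolite_gm / MG_PER_L_TO_NG_PER_ML
            * physiology.daily_urine_volume
            * frac
            / (physiology.body_weight * y * f_abs)
        )
    return out
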