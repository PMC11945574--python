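# Methods

`pyrethro` reconstructs population exposure to pyrethroid insecticides from
left-censored urinary biomarker surveys and carries the reconstruction
through to margin-of-exposure risk estimates. This note documents the
models, the numerical choices, and what the synthetic-data experiments do
and do not demonstrate.

## Chemical bookkeeping

Four parent pyrethroids (deltamethrin, permethrin, cypermethrin,
cyfluthrin; the latter three as cis/trans isomer pairs with a fixed
40%/60% composition) map onto urinary carboxylic-acid metabolites through
molar transformation fractions φ(p → m). FPBA is specific to cyfluthrin
and DBCA to deltamethrin; 3PBA and the DCCA isomers are shared. The
registry validates mass balance (Σ_m φ(p → m) ≤ 1 per parent; the
remainder is other elimination) and converts molar fractions to mass
yields φ·MW_m/MW_p. Two unmeasured downstream metabolites (a hydroxylated
phenoxybenzoic acid and a benzyl-alcohol intermediate) are carried in the
registry but excluded from likelihoods; they keep further-metabolism
sensitivity analyses expressible, since DCCA in particular can be
metabolized onward and its loss would bias intakes low.

The default φ values ship as a versioned CSV. They are order-of-magnitude
representative of published human balance data for these compounds; no
result in the test suite depends on their exact values, because synthetic
truths are always pushed through the same registry used for inference.
Cypermethrin has no specific biomarker; its intake is tied to permethrin
by a fixed ratio (default 0.1, configurable), informed by relative use
patterns.

## Kinetics

The compartmental model has a gut lumen with competing first-order
absorption (ka) and fecal elimination (kf), a plasma central compartment,
flow-limited liver / fat / richly- and slowly-perfused tissues, a
permeability-limited brain (PA·fu driving force), hepatic metabolism on
the liver venous concentration (CL·fu·C_liver/P_liver) splitting the
parent into metabolites by mass yield, and one-compartment metabolite
kinetics with first-order urinary elimination. Default parameters give
urinary metabolite half-lives of roughly 6–13 h, matching the observation
that these compounds clear within a day. Cyfluthrin and cypermethrin
reuse deltamethrin's chemical-specific values, as no compound-specific
human kinetic data support separate ones.

Integration uses LSODA with rtol 1e-8 / atol 1e-10 (absorption phases
against slow deep-tissue equilibration make the system stiff); AUC is
trapezoidal on the solver grid; bolus events split the integration so
jumps stay exact. Parent mass balance (dosed = in-body + fecal +
metabolized) is checked on every simulation and holds to ~1e-15 relative.

Under constant intake the system converges to an analytical steady state:
because the only parent exits are feces and metabolism, and the only
metabolite exit is urine, the steady-state urine concentration is

    C_m = Σ_p intake_p · BW · f_abs,p · φ(p→m) · (MW_m/MW_p) / V_urine

with f_abs = ka/(ka+kf), and daily creatinine replacing V_urine under
creatinine normalization. This linear map — not the ODE — drives the
inference, exactly because spot samples carry no timing information and a
steady-state reading is the only defensible one. The ODE exists to
validate the map (agreement to ≤1% after ≥10 half-lives across random
parameter draws is part of the acceptance suite, and reaches ~1e-10 at
numerical convergence), to compute rat dose metrics at the benchmark
dose, and to propagate Monte Carlo uncertainty into human Cmax/AUC.

The approach to steady state is governed by the slowest of: whole-body
elimination CL·fu/Vss, metabolite washout 1/k_urine, and deep-tissue fill
times V_t·P_t/Q_t — for fat at P ≈ 100 the latter dominates at ~100 h.
Validation simulations size their duration from that timescale.

The packaged rat parameterization is synthetic (so labelled in its
filename and header): a stand-in with literature-plausible rat kinetics
used to exercise the systemic point-of-departure machinery, not a
transcription of a published rat model. Dose metrics computed from it are
internally consistent but not comparable to published rat values.

## Survey model and descriptive statistics

A survey is a long table of (subject, metabolite) records with the
concentration, the metabolite- and cycle-specific LOD, and a censoring
flag. Descriptive statistics substitute LOD/√2 for non-detects (LOD/2 and
0 selectable); inference never substitutes. P95/P50 uses type-7 linear
interpolation — stated because the ratio on small strata is sensitive to
the quantile rule — and converges to GSD^1.6449 for lognormal data.
Age-group similarity clusters log10 median exposures over cycles with
Euclidean distance and average linkage. Survey weights are accepted as a
column but default to 1; no complex-design estimation is attempted.

## Bayesian reverse dosimetry

Per stratum (age group × cycle), individual i carries a latent daily
intake exp(u_gi) of each free parent group g:

    u_gi ~ Normal(mu_g, sigma2_g)
    mu_g ~ Uniform on log10 intake over [−12, 0] mg/kg/day
    sigma2_g ~ Inverse-Gamma(shape 5, scale 2.25)      (prior mean 0.5625 → GSD ≈ 2)
    sigma2_res,m ~ Half-Normal(scale 0.3)              (scale value → GSD ≈ 1.7)

Detected concentrations are lognormal around the steady-state prediction
with per-metabolite residual variance. Non-detects contribute a normal
density with sd = LOD/4 evaluated at an imputed value — 0 or LOD/2, run
as a sensitivity pair, never a hybrid. The uniform prior is placed on
log10 intake: a natural-scale uniform over 24 decades would concentrate
essentially all prior mass in the top decade and be informative in the
worst way. Population GSDs are reported as exp(√variance) with variances
on the natural-log scale, which reproduces both stated prior
correspondences (0.5625 → 2, 0.3 → 1.7).

Sampling is Metropolis-within-Gibbs with three chains: vectorized
single-site Metropolis on the latents (step adapted to ~35% acceptance
during burn-in; three sweeps per stored iteration, which shortens the
autocorrelation of the residual sum of squares — compound-specific
biomarkers otherwise let each latent chase its single record and the
residual variance mixes through a funnel), truncated-normal Gibbs for
mu_g, conjugate inverse-gamma Gibbs for sigma2_g, and a scalar Metropolis
step on log sigma2_res (five sub-steps; the half-normal prior is not
conjugate). Defaults: 3 chains × 10,000 iterations, 50% burn-in, explicit
seed. Convergence is judged by split-R̂ < 1.1 on every stored parameter
(cross-checked against an independent implementation in the test suite),
with a zero-variance guard defining R̂ = 1 for constant identical chains.
Strata are fitted independently — population medians are not shared
across cycles, matching how per-cycle results are reported. Body weight
enters per individual where the table provides it, falling back to the
age-group reference.

### What the censoring device does to calibration

On uncensored synthetic data the sampler is well calibrated: across
replicate surveys the 90% credible interval covers the true population
median ~94% of the time with bias < 0.002 log10. Under 30% censoring the
imputed-value device is not a censored likelihood: it pulls censored
latents toward the imputed value instead of integrating the lognormal
tail, producing a systematic ≈ −0.1 log10 bias for the LOD/2 policy
(≈ −0.37 for the zero policy) that exceeds the ±0.03 interval half-width
at n = 500 per stratum. Point recovery therefore stays well within
±0.3 log10, but interval coverage collapses, and the corresponding
acceptance test is expected to fail — a property of the device itself,
deliberately retained rather than silently replaced by a censored-CDF
likelihood. The policy pair (0 vs LOD/2) brackets the sensitivity of the
inference to non-detect handling, which is its purpose.

### High-throughput comparator

The simplified route fits a left-censored lognormal to the urine
concentrations by maximum likelihood (detected values contribute
densities, censored records the mass below their LOD; the no-censoring
limit reduces exactly to the sample GM and GSD), then inverts the
steady-state map: intake = GM·V_urine/(BW·yield·f_abs), apportioned
across parents by attribution fractions for shared metabolites. On clean
data the full-Bayes and high-throughput estimates agree within 2×, which
is the idealized form of their observed concordance.

## Benchmark dose

Dose-response data are group summaries (dose, n, mean, SD) of a
continuous endpoint, fitted with the normal sufficient-statistics
likelihood under eight families: linear, power, 2nd-order polynomial,
Hill, and exponential 2–5 (shape exponents and asymptotes kept in
constrained parameterizations via log/logit transforms). The benchmark
response is a downward shift of one control SD — implemented as a mean
shift, the common default — and the BMD solves f(0) − f(BMD) = σ per
posterior draw by bracketed root-finding; draws with no crossing below
10× the top dose are recorded as unbounded and a fit with a substantial
unbounded fraction is flagged.

Priors are weakly informative and data-scaled at roughly unit-information
strength (intercepts at the control mean with sd of about twice the
response span; slopes scaled to span/dose-range; shape exponents
lognormal around 1). The scaling matters: with arbitrarily diffuse priors
the marginal likelihoods — and hence the model weights — are dominated by
prior volume rather than fit, and on exactly-linear data curved families
can win by accident of prior width.

Each family runs three adaptive-Metropolis chains (covariance adapted
during the first half, frozen after); the kept half of the chains feeds a
Gelfand–Dey marginal-likelihood estimate (an importance-weighted average
with a multivariate-normal weighting density matched to the posterior —
the stabilized form of the harmonic mean). Non-converged families
(split-R̂ ≥ 1.1) are excluded from averaging with a warning. The averaged
BMD posterior is the weight-resampled mixture of per-model BMD draws;
BMD is its median and BMDL the 5th percentile (one-sided 95% lower
bound, the regulatory convention). Averaging over a single model is the
identity, and the 1-SD benchmark response is invariant under
location-scale transformations of the response.

The reference configuration is 30,000 iterations per chain with the last
half kept; the test suite and acceptance script use 4,000–8,000, which
the closed-form checks show is past the point of diminishing returns for
these small design matrices.

## Margins

MOE = BMDL / intake (mg/kg over mg/kg/day), element-wise over intake
draws when a distribution is supplied. MOIE = systemic POD metric / human
dose metric, where the POD metrics (Cmax and AUC in plasma and brain) are
simulated in the rat model at a single oral dose equal to the BMDL, and
the human metrics come from Monte Carlo single-day simulations at the
reconstructed intake. Which exposure summary feeds the margin is a
configuration switch (GM, P95, P99; the conservative top-percentile
convention is the pipeline default). A margin passes when its 5th
percentile meets the target; the default target is 100 (10×10
uncertainty factors) and a stricter 10⁴ is configurable. Because the
kinetics are linear in dose, margins are exactly inversely proportional
to intake, and AUC-based internal margins are invariant to the
integration window.

## Synthetic data

The survey generator is the population model run forward: lognormal body
weights per age group (fixed reference GM/GSD shipped with the package),
lognormal latent intakes, the linear steady-state map, a multiplicative
lognormal residual, and left-censoring at (metabolite, cycle) LODs. The
default scenario mirrors the survey structure being emulated: seven
biennial cycles, five age groups, five metabolites with coverage
shrinking over time (cis-DCCA and DBCA phased out; the final cycle
carries three analytes), LODs varying by cycle, children's intakes about
two-fold above adults', and a doubling time trend. A calibration helper
places LODs at a requested censoring quantile using a large uncensored
sample from the same generator.

What passing tests show: the inference recovers the parameters of the
data-generating process it assumes, at survey-realistic sizes, censoring
levels, and noise. What they do not show: robustness to non-steady-state
exposure (within-day peaks of spot samples can exceed the daily average
two- to three-fold; an optional multiplicative peak-factor term exists
but defaults to off), to non-lognormal population tails, to survey
weighting, or to misspecified transformation fractions. Dose-response
truths record their analytic BMD (SD/|slope| for the linear family;
bracketed root-finding otherwise, cross-checked to 1e-6).

## Problem sizes

Reference analyses in the repository run at: recovery surveys of 500
individuals per stratum with 20 replicate surveys for interval-coverage
estimation; 50 random kinetic draws for the ODE/steady-state oracle;
n = 10⁴ for censored-lognormal recovery and n = 10⁵ for quantile-ratio
closed forms; 8 × 3 chains × 4,000 iterations for the benchmark-dose
averaging checks. These sizes put Monte Carlo error comfortably inside
each check's tolerance.

## Known limitations

- Transformation fractions and life-stage physiology are representative
  defaults, not fitted values; both are config-overridable and the
  honest uncertainty in them propagates directly (the map is linear).
- The below-LOD device biases population medians under heavy censoring
  (see above); the package exposes both policies so the bias is visible
  as a sensitivity range rather than hidden.
- Dermal and inhalation routes are forward-simulation only; reconstruction
  assumes oral dominance.
- No cumulative multi-compound index is computed; margins are
  per-compound.
- The rat parameterization is a synthetic stand-in; systemic margins are
  demonstrations of the machinery until a calibrated rat model is
  supplied via `load_rat_model(path)`.
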