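# pyrethro

Biomonitoring-based risk assessment of pyrethroid insecticide exposure:
Bayesian reverse dosimetry from left-censored urinary metabolite surveys,
model-averaged benchmark doses for acute neurotoxicity, and external /
internal margins of exposure.

The package is written for exposure scientists and risk assessors who
have population spot-urine measurements of pyrethroid metabolites (3PBA,
FPBA, DBCA, cis-/trans-DCCA) with per-record limits of detection, and who
want defensible estimates of parent-compound daily intakes (deltamethrin,
permethrin, cypermethrin, cyfluthrin) and of the margins separating those
intakes — and the internal doses they imply — from neurotoxic points of
departure.

## The model in brief

Spot urine samples carry no exposure-timing information, so each
observation is read as a steady-state concentration under constant daily
intake. Steady state makes the intake-to-biomarker map linear and
analytical:

    C_m = Σ_p D_p · BW · f_abs,p · φ(p→m) · (MW_m / MW_p) / V_urine

with D_p the intake (mg/kg/day), f_abs = ka/(ka+kf) the oral absorbed
fraction, and φ(p→m) the molar transformation fraction of parent p into
metabolite m. The map is embedded in a hierarchical population model per
survey stratum (age group × cycle):

    u_i ~ N(μ, σ²_pop)              latent log intake per individual
    μ   ~ Uniform(log10 ∈ [−12, 0]) population median intake
    σ²_pop ~ Inv-Gamma(5, 2.25)     population variance (prior GSD ≈ 2)
    σ²_res ~ Half-N(0.3)            residual variance (GSD ≈ 1.7)

Detected values are lognormal around the prediction; non-detects enter
through a normal density at an imputed value (0 or LOD/2, a sensitivity
pair) with sd = LOD/4. Sampling is Metropolis-within-Gibbs over three
chains with split-R̂ < 1.1 as the convergence gate.

Downstream, continuous dose-response data (locomotor activity) are fitted
by MCMC under eight standard families and combined by posterior model
weights into a model-averaged BMD; the BMDL (5th percentile) at a
benchmark response of one control SD is the point of departure.
MOE = BMDL / intake; MOIE = rat-PBK dose metric at the BMDL (Cmax or AUC,
plasma or brain) / the Monte-Carlo human dose metric. A full
compartmental PBK model (gut, plasma, liver, fat, permeability-limited
brain, perfusion-limited remainder, metabolite urinary excretion)
validates the steady-state map and supplies the dose metrics.

A known-truth synthetic-data generator emulates the survey structure the
analysis assumes — seven biennial cycles, five age groups, cycle-varying
LODs, metabolite phase-outs — so every stage is testable against ground
truth. See `docs/methods.md` for assumptions, priors, numerical choices,
and known limitations.

## Worked example

Generate a known-truth survey (300 individuals, ~20% non-detects, true
permethrin intake 1e-05 mg/kg/day), reconstruct intakes, and compute a
margin of exposure:

```python
import numpy as np
from pyrethro import chem_map, pbk, reverse_dosimetry as rd, synthetic_data as sd, risk

registry = chem_map.default_registry()
params = pbk.load_pbk_parameters()
physiology = {a: pbk.Physiology.reference(a) for a in pbk.AGE_GROUPS}

truth = sd.recovery_truth(seed=1, n_per_stratum=300, censored_fraction=0.2,
                          registry=registry, params=params)
table, _ = sd.generate_survey(truth, registry, params)
print(f"survey records: {len(table)}, censored: {table.frame.below_lod.mean():.0%}")

draws = rd.sample_posterior(table, registry, params, physiology,
                            iterations=4000, seed=2)
summary = draws.summary()
row = summary[summary.parameter == "log10_intake[permethrin|6-11|2001-2002]"].iloc[0]
print(f"permethrin GM intake: {10**row['median']:.2e} mg/kg/day "
      f"(90% CI {10**row.ci5:.2e} - {10**row.ci95:.2e}; truth 1.00e-05)")
print(f"max R-hat: {max(draws.convergence().rhat.values()):.3f}")

moe = risk.compute_moe(39.17, 10**row["median"], target=1e4)
print(f"MOE vs permethrin BMDL 39.17 mg/kg: {moe.median:,.0f}")
```

Output:

```
survey records: 1500, censored: 21%
permethrin GM intake: 7.07e-06 mg/kg/day (90% CI 6.25e-06 - 7.92e-06; truth 1.00e-05)
max R-hat: 1.020
MOE vs permethrin BMDL 39.17 mg/kg: 5,541,003
```

The reconstructed geometric mean lands within a factor of ~1.4 of truth
(the credible interval reflects sampling of 300 individuals; the slight
low bias is the documented effect of the below-LOD imputation device).
The margin of 5.5 million means the estimated intake sits far below the
permethrin point of departure — margins above the 10⁴ target are read as
acceptable acute risk.

The same stages are available from the shell:

```
$ pyrethro simulate --compound deltamethrin --dose 1.79 --duration 48 --out tc.csv
Cmax plasma 373.3 ng/mL, AUC plasma 2068 ng-h/mL, Cmax brain 329.4 ng/g, AUC brain 5043 ng-h/g

$ pyrethro synth --out data/ --seed 1
$ pyrethro reconstruct --table data/survey.csv --seed 2 --iters 4000
$ pyrethro bmd --data doseresponse.csv --seed 3
$ pyrethro run --config pipeline.toml     # all four stages + run manifest
```

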