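"""Bayesian intake reconstruction: likelihood, sampler, diagnostics, comparator."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from pyrethro import chem_map, pbk, reverse_dosimetry as rd, synthetic_data as sd
from pyrethro._mcmc import split_rhat
from pyrethro.errors import ConfigurationError, DomainError, ValidationError


class TestPriorSpec:
    def test_residual_scale_implies_gsd_1_7(self):
        assert round(rd.PriorSpec().residual_gsd, 1) == 1.7

    def test_inverse_gamma_prior_mean_implies_gsd_2(self):
        assert round(rd.PriorSpec().prior_mean_pop_gsd) == 2

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValidationError):
            rd.PriorSpec(log10_intake_low=0.0, log10_intake_high=-12.0)


class TestLogLikelihood:
    def test_detected_at_prediction_is_lognormal_maximum(self):
        obs, sd = 2.5, 0.4
        ll = rd.log_likelihood(obs, False, 0.1, obs, sd)
        assert ll == pytest.approx(-math.log(obs * sd * math.sqrt(2 * math.pi)))
        # any other observation has lower density
        assert rd.log_likelihood(obs * 1.5, False, 0.1, obs, sd) < ll

    def test_censored_centered_case(self):
        ll = rd.log_likelihood(None, True, 0.1, 0.05, 0.3, lod_policy="half_lod")
        assert ll == pytest.approx(norm.logpdf(0.05, 0.05, 0.025))

    def test_zero_policy_evaluates_at_zero(self):
        ll = rd.log_likelihood(None, True, 0.1, 0.05, 0.3, lod_policy="zero")
        assert ll == pytest.approx(norm.logpdf(0.0, 0.05, 0.025))

    def test_likelihood_diverges_as_residual_sd_vanishes(self):
        lls = [rd.log_likelihood(2.0, False, 0.1, 1.0, s) for s in (0.5, 0.1, 0.02)]
        assert lls[0] > lls[1] > lls[2]

    def test_nonpositive_prediction_rejected(self):
        with pytest.raises(DomainError):
            rd.log_likelihood(1.0, False, 0.1, 0.0, 0.3)


class TestGelmanRubin:
    def test_chains_from_common_target_near_one(self, rng):
        chains = rng.standard_normal((3, 10_000))
        r = split_rhat(chains)
        assert r == pytest.approx(1.0, abs=0.01)

    def test_offset_chains_flagged(self, rng):
        chains = rng.standard_normal((2, 500))
        chains[1] += 10.0
        assert split_rhat(chains) > 1.5

    def test_constant_identical_chains_convention(self):
        assert split_rhat(np.ones((3, 100))) == 1.0

    def test_single_chain_rejected(self):
        with pytest.raises(DomainError):
            split_rhat(np.ones((1, 100)))

    def test_matches_arviz_on_well_mixed_chains(self, rng):
        arviz = pytest.importorskip("arviz")
        chains = rng.standard_normal((3, 2000)) + 0.05 * rng.standard_normal((3, 1))
        ours = split_rhat(chains)
        theirs = float(arviz.rhat(arviz.convert_to_dataset(chains))["x"].values)
        assert ours == pytest.approx(theirs, abs=0.01)

    def test_report_pass_flag(self, rng):
        good = rng.standard_normal((3, 1000))
        rep = rd.gelman_rubin({"a": good})
        assert rep.passed and rep.rhat["a"] < 1.1


def _recovery_table(seed, n=400, lod=0.05, residual_gsd=1.2):
    registry = chem_map.default_registry()
    params = pbk.load_pbk_parameters()
    truth = sd.GeneratorTruth(
        intake={
            (g, "6-11", "2001-2002"): (1e-5, 2.0)
            for g in ("deltamethrin", "permethrin", "cyfluthrin")
        },
        residual_gsd=residual_gsd,
        lods={(m, "2001-2002"): lod for m in chem_map.MEASURED_METABOLITES},
        n_per_stratum=n,
        seed=seed,
    )
    table, _ = sd.generate_survey(truth, registry, params)
    return table, registry, params


class TestSamplePosterior:
    def test_parameter_recovery_single_stratum(self, physiology_by_age):
        table, registry, params = _recovery_table(seed=42)
        draws = rd.sample_posterior(
            table, registry, params, physiology_by_age, iterations=3000, seed=7
        )
        for g in ("deltamethrin", "permethrin", "cyfluthrin"):
            med = np.median(draws.draws[f"log10_intake[{g}|6-11|2001-2002]"])
            assert med == pytest.approx(-5.0, abs=0.3)

    def test_noise_free_uncensored_posterior_concentrates(self, physiology_by_age):
        table, registry, params = _recovery_table(seed=1, n=1000, lod=1e-9, residual_gsd=1.0)
        draws = rd.sample_posterior(
            table, registry, params, physiology_by_age, iterations=3000, seed=3
        )
        for g in ("deltamethrin", "permethrin", "cyfluthrin"):
            arr = draws.draws[f"log10_intake[{g}|{'6-11'}|2001-2002]"].reshape(-1)
            q25, q75 = np.percentile(arr, [25, 75])
            assert q75 - q25 < 0.05

    def test_same_seed_identical_draws(self, physiology_by_age):
        table, registry, params = _recovery_table(seed=2, n=60)
        a = rd.sample_posterior(table, registry, params, physiology_by_age, iterations=400, seed=9)
        b = rd.sample_posterior(table, registry, params, physiology_by_age, iterations=400, seed=9)
        for k in a.draws:
            assert np.array_equal(a.draws[k], b.draws[k])

    def test_unmapped_metabolite_rejected_before_sampling(
        self, single_pathway_registry, physiology_by_age
    ):
        table, registry, params = _recovery_table(seed=3, n=20)
        with pytest.raises(ConfigurationError):
            rd.sample_posterior(
                table, single_pathway_registry, None, physiology_by_age, iterations=100, seed=0
            )


class TestCensoredLognormalFit:
    def test_no_censoring_closed_form(self):
        vals = np.array([1.0, 10.0, 100.0])
        fit = rd.censored_lognormal_fit(vals, np.zeros(3, bool), np.full(3, 0.01))
        assert fit.gm == pytest.approx(10.0)
        assert fit.gsd == pytest.approx(float(np.exp(np.std(np.log(vals), ddof=1))))

    def test_monte_carlo_recovery_under_half_censoring(self, rng):
        x = np.exp(rng.standard_normal(10_000) * np.log(2.0))
        lod = float(np.median(x))
        cens = x < lod
        fit = rd.censored_lognormal_fit(np.where(cens, 0, x), cens, np.full(x.size, lod))
        assert fit.gm == pytest.approx(1.0, rel=0.03)
        assert fit.gsd == pytest.approx(2.0, rel=0.03)

    def test_vanishing_censoring_limit_matches_uncensored_estimator(self, rng):
        x = np.exp(rng.standard_normal(500) * 0.7 + 0.2)
        cens = np.zeros(x.size, bool)
        lods = np.full(x.size, x.min() / 10)
        fit = rd.censored_lognormal_fit(x, cens, lods)
        assert fit.gm == pytest.approx(float(np.exp(np.mean(np.log(x)))))

    def test_all_censored_gives_bound_only(self):
        fit = rd.censored_lognormal_fit(np.zeros(5), np.ones(5, bool), np.full(5, 0.1))
        assert fit.all_censored and fit.gm is None and fit.upper_bound == pytest.approx(0.1)
        with pytest.raises(DomainError):
            fit.cdf_report()


class TestHtIntakeEstimate:
    def test_inverts_the_steady_state_map(self, single_pathway_registry, adult):
        reg = single_pathway_registry
        ss = pbk.steady_state_urine({"deltamethrin": 1e-3}, reg, None, adult)
        est = rd.ht_intake_estimate(ss["DBCA"], "DBCA", reg, adult)
        assert est["deltamethrin"] == pytest.approx(1e-3)

    def test_zero_gm_gives_zero_intake(self, single_pathway_registry, adult):
        est = rd.ht_intake_estimate(0.0, "DBCA", single_pathway_registry, adult)
        assert est["deltamethrin"] == 0.0

    def test_halving_mass_yield_doubles_intake(self, adult):
        compounds = [chem_map.CompoundSpec("deltamethrin", 505.2, "deltamethrin")]
        mets = [
            chem_map.MetaboliteSpec(m, 298.0) for m in chem_map.MEASURED_METABOLITES
        ]
        full = chem_map.validate_registry(
            compounds, mets, chem_map.TransformationMatrix({("deltamethrin", "DBCA"): 0.4})
        )
        half = chem_map.validate_registry(
            compounds, mets, chem_map.TransformationMatrix({("deltamethrin", "DBCA"): 0.2})
        )
        e1 = rd.ht_intake_estimate(5.0, "DBCA", full, adult)["deltamethrin"]
        e2 = rd.ht_intake_estimate(5.0, "DBCA", half, adult)["deltamethrin"]
        assert e2 == pytest.approx(2 * e1)

    def test_shared_metabolite_requires_attribution(self, registry, adult):
        with pytest.raises(ConfigurationError):
            rd.ht_intake_estimate(1.0, "3PBA", registry, adult)


def test_full_bayes_and_ht_agree_on_clean_data(physiology_by_age):
    """The two reverse-dosimetry routes agree within 2x without censoring/noise."""
    table, registry, params = _recovery_table(seed=5, n=800, lod=1e-9, residual_gsd=1.0)
    draws = rd.sample_posterior(
        table, registry, params, physiology_by_age, iterations=2000, seed=1
    )
    phys = physiology_by_age["6-11"]
    vals = table.frame[table.frame.metabolite == "DBCA"]
    fit = rd.censored_lognormal_fit(
        vals.value.to_numpy(), vals.below_lod.to_numpy(), vals.lod.to_numpy()
    )
    ht = rd.ht_intake_estimate(fit.gm, "DBCA", registry, phys, params=params)["deltamethrin"]
    bayes = 10 ** float(np.median(draws.draws["log10_intake[deltamethrin|6-11|2001-2002]"]))
    assert 0.5 < ht / bayes < 2.0
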