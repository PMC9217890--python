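"""Lognormal transforms, truncated sampling, Monte Carlo and CSAFs."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from methadone_qivive import cyp, pbk, population
from methadone_qivive.cyp import AbundanceDistribution
from methadone_qivive.population import (
    LognormalSpec,
    PopulationDistribution,
    derive_csaf,
    individual_models_cmax,
    lognormal_params,
    monte_carlo_cmax,
    sample_truncated,
)


class TestLognormalTransform:
    def test_zero_cv(self):
        spec = lognormal_params(42.0, 0.0)
        assert spec.sigma_omega == 0.0
        assert spec.mu_omega == pytest.approx(math.log(42.0), rel=1e-15)

    def test_reference_abundance_values(self):
        # CYP3A4 Caucasian: mean 93, CV 0.81
        spec = lognormal_params(93.0, 0.81)
        assert spec.mu_omega == pytest.approx(4.2804, abs=2e-4)
        assert spec.sigma_omega == pytest.approx(0.7103, abs=2e-4)
        # CYP2B6 EM Caucasian: mean 17, CV 1.22
        spec = lognormal_params(17.0, 1.22)
        assert spec.mu_omega == pytest.approx(2.3773, abs=2e-4)
        assert spec.sigma_omega == pytest.approx(0.9548, abs=2e-4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(mu=st.floats(0.01, 1e3), cv=st.floats(0.0, 3.0))
    def test_roundtrip_identities(self, mu, cv):
        """The log-scale parameters reproduce the untransformed mean and CV
        through the lognormal moment identities, to 1e-12."""
        spec = lognormal_params(mu, cv)
        mean_back = math.exp(spec.mu_omega + spec.sigma_omega ** 2 / 2.0)
        var_back = (math.exp(spec.sigma_omega ** 2) - 1.0) * mean_back ** 2
        assert mean_back == pytest.approx(mu, rel=1e-12)
        assert math.sqrt(var_back) == pytest.approx(mu * cv, rel=1e-9, abs=1e-12)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            lognormal_params(0.0, 0.5)


class TestTruncatedSampling:
    def test_zero_cv_collapses(self):
        assert np.all(sample_truncated(lognormal_params(5.0, 0.0), 10, 0) == 5.0)

    def test_truncation_bounds_respected(self):
        spec = lognormal_params(17.0, 1.22)
        x = sample_truncated(spec, 20000, 123)
        sd = 17.0 * 1.22
        assert x.min() >= 17.0 - 3 * sd
        assert x.max() <= 17.0 + 3 * sd

    def test_seeded_streams_reproducible(self):
        spec = lognormal_params(93.0, 0.81)
        a = sample_truncated(spec, 1000, 7)
        b = sample_truncated(spec, 1000, 7)
        assert np.array_equal(a, b)

    def test_large_sample_gm_matches_truncated_oracle(self):
        """Sample GM of 1e5 draws vs the truncated-lognormal log-mean
        computed analytically (truncation mapped to the log scale)."""
        spec = lognormal_params(93.0, 0.81)
        x = sample_truncated(spec, 100_000, 99)
        lo, hi = 93.0 * (1 - 3 * 0.81), 93.0 * (1 + 3 * 0.81)
        a = -np.inf if lo <= 0 else (math.log(lo) - spec.mu_omega) / spec.sigma_omega
        b = (math.log(hi) - spec.mu_omega) / spec.sigma_omega
        log_mean = stats.truncnorm.mean(a, b, loc=spec.mu_omega,
                                        scale=spec.sigma_omega)
        assert np.exp(np.log(x).mean()) == pytest.approx(np.exp(log_mean), rel=0.01)


def _lognormal_dist(mu, sigma, n, seed, **kw):
    rng = np.random.default_rng(seed)
    samples = rng.lognormal(mu, sigma, n)
    defaults = dict(scenario="metabolism_only", population="Caucasian",
                    enantiomer="R")
    defaults.update(kw)
    return PopulationDistribution(
        samples=samples, weights=np.full(n, 1.0 / n), **defaults)


class TestDistributionAndCsaf:
    def test_gm_and_gcv_of_lognormal_sample(self):
        d = _lognormal_dist(math.log(2.0), 0.5, 200_000, 3)
        assert d.gm == pytest.approx(2.0, rel=0.01)
        assert d.gcv == pytest.approx(math.sqrt(math.expm1(0.25)), rel=0.02)

    def test_percentile_ordering(self):
        d = _lognormal_dist(0.0, 0.7, 50_000, 4)
        assert d.p95 <= d.p99

    def test_pooled_percentile_between_strata(self):
        """Mixture percentiles lie between the per-stratum percentiles."""
        rng = np.random.default_rng(5)
        a = rng.lognormal(0.0, 0.5, 4000)
        b = rng.lognormal(1.0, 0.5, 4000)
        pooled = PopulationDistribution(
            samples=np.concatenate([a, b]),
            weights=np.concatenate([np.full(4000, 0.89 / 4000),
                                    np.full(4000, 0.11 / 4000)]),
            scenario="metabolism_only", population="Caucasian", enantiomer="R",
            strata={"EM": (4000, 0.89), "PM": (4000, 0.11)},
        )
        for q in (95.0, 99.0):
            lo = min(np.percentile(a, q), np.percentile(b, q))
            hi = max(np.percentile(a, q), np.percentile(b, q))
            assert lo <= pooled.percentile(q) <= hi

    def test_parameter_weighted_percentile_close_to_pooled_for_one_stratum(self):
        d = _lognormal_dist(0.0, 0.5, 50_000, 6)
        d.strata = {"EM": (50_000, 1.0)}
        assert d.percentile_parameter_weighted(99) == pytest.approx(d.p99, rel=0.03)

    def test_within_population_csaf_at_least_one(self):
        d = _lognormal_dist(1.0, 0.6, 20_000, 8)
        for p in (95, 99):
            r = derive_csaf(d, p)
            assert r.csaf >= 1.0
            assert r.basis == "within_caucasian"

    def test_combined_basis_uses_reference_gm(self):
        d = _lognormal_dist(1.0, 0.5, 10_000, 9)
        ref = _lognormal_dist(0.0, 0.5, 10_000, 10)
        r = derive_csaf(d, 99, reference=ref)
        assert r.basis == "combined"
        assert r.csaf == pytest.approx(d.p99 / ref.gm, rel=1e-12)

    def test_ipcs_flag(self):
        d = _lognormal_dist(0.0, 1.0, 20_000, 11)
        assert derive_csaf(d, 99).exceeds_ipcs_default  # exp(2.33) >> 3.16

    def test_invalid_percentile_rejected(self):
        d = _lognormal_dist(0.0, 0.5, 100, 12)
        with pytest.raises(ValueError):
            derive_csaf(d, 50)


class TestMonteCarlo:
    def test_zero_cv_collapses_to_deterministic(self, monkeypatch):
        """With all abundance CVs forced to zero the Monte Carlo
        distribution equals the deterministic recombinant-CYP model."""
        real = cyp.abundance_distributions

        def degenerate(populationname, isoform):
            return [AbundanceDistribution(
                isoform=isoform, phenotype="general", frequency=1.0,
                mean_abundance=cyp.phenotype_weighted_abundance(
                    real(populationname, isoform)),
                cv=0.0,
            )]

        monkeypatch.setattr(population.cyp, "abundance_distributions", degenerate)
        d = monte_carlo_cmax("Caucasian", "R", "metabolism_only",
                             n_per_stratum=2, seed=1, n_days=20)
        assert d.gcv == pytest.approx(0.0, abs=1e-9)
        spec = cyp.rcyp_metabolism_spec(
            "Caucasian", "R",
            abundances={iso: degenerate("Caucasian", iso)[0].mean_abundance
                        for iso in cyp.ISOFORMS})
        params = pbk.default_parameters("Caucasian", "R", spec)
        res = pbk.simulate(params, 30.0, 20, rtol=1e-6, atol=1e-8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", pbk.SteadyStateWarning)
            _, unbound = pbk.steady_state_cmax(res)
        assert d.gm == pytest.approx(unbound, rel=0.005)

    def test_metabolism_only_gm_near_weighted_abundance_model(self):
        """The Monte Carlo GM stays close to the deterministic prediction at
        phenotype-weighted mean abundances (nonlinearity keeps them from
        coinciding exactly)."""
        d = monte_carlo_cmax("Caucasian", "R", "metabolism_only",
                             n_per_stratum=300, seed=2, n_days=20)
        params = pbk.default_parameters(
            "Caucasian", "R", cyp.rcyp_metabolism_spec("Caucasian", "R"))
        res = pbk.simulate(params, 30.0, 20, rtol=1e-6, atol=1e-8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", pbk.SteadyStateWarning)
            _, unbound = pbk.steady_state_cmax(res)
        assert d.gm == pytest.approx(unbound, rel=0.2)

    def test_multifactor_spreads_more_than_metabolism_only(self):
        a = monte_carlo_cmax("Caucasian", "R", "metabolism_only",
                             n_per_stratum=200, seed=3, n_days=20)
        b = monte_carlo_cmax("Caucasian", "R", "multifactor",
                             n_per_stratum=200, seed=3, n_days=20)
        assert b.gcv > a.gcv

    def test_seeded_reproducibility(self):
        a = monte_carlo_cmax("Caucasian", "R", "metabolism_only",
                             n_per_stratum=50, seed=4, n_days=10)
        b = monte_carlo_cmax("Caucasian", "R", "metabolism_only",
                             n_per_stratum=50, seed=4, n_days=10)
        assert np.array_equal(a.samples, b.samples)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_cmax("Caucasian", "R", "everything", 10, 1)


class TestIndividualModels:
    def test_identical_fits_have_zero_gcv(self):
        from methadone_qivive.kinetics import MMKinetics

        fits = [MMKinetics(vmax=0.4, km=155.0)] * 5
        d = individual_models_cmax(fits, "Caucasian", "R", n_days=15)
        assert d.gcv == pytest.approx(0.0, abs=1e-9)
        assert d.scenario == "individual_models"

    def test_cmax_inversely_ordered_with_efficiency(self):
        from methadone_qivive.kinetics import MMKinetics

        fits = [MMKinetics(vmax=v, km=155.0) for v in (0.1, 0.2, 0.4, 0.8)]
        d = individual_models_cmax(fits, "Caucasian", "R", n_days=15)
        assert np.all(np.diff(d.samples) < 0)  # more conversion, less Cmax

    def test_r_varies_less_than_s_in_calibrated_caucasian_donors(self):
        """Synthetic 25-donor Caucasian sets: the geometric CV of unbound
        Cmax is smaller for R- than for S-methadone, mirroring the smaller
        in vitro variability of R-EDDP formation."""
        from methadone_qivive.kinetics import MMKinetics
        from methadone_qivive.synthetic import profile_from_reference
        from methadone_qivive.population import sample_truncated

        dists = {}
        for en in ("R", "S"):
            prof = profile_from_reference("Caucasian", en)
            rng = np.random.default_rng(21)
            vmax = sample_truncated(
                lognormal_params(prof.mean_vmax, prof.cv_vmax), 25, rng)
            km = sample_truncated(
                lognormal_params(prof.mean_km, prof.cv_km), 25, rng)
            fits = [MMKinetics(vmax=v, km=k) for v, k in zip(vmax, km)]
            dists[en] = individual_models_cmax(fits, "Caucasian", en, n_days=20)
        assert dists["R"].gcv < dists["S"].gcv

    def test_too_few_individuals_rejected(self):
        from methadone_qivive.kinetics import MMKinetics

        with pytest.raises(ValueError):
            individual_models_cmax([MMKinetics(vmax=0.4, km=155.0)],
                                   "Caucasian", "R")
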