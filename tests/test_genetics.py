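import numpy as np
import pytest
from scipy import stats

from methaphen.genetics import (ModelSpec, PosteriorDraws, build_a_inverse,
                                component_correlations, gibbs_bivariate,
                                gibbs_univariate, herd_fraction, heritability,
                                posterior_summaries)
from methaphen.pedigree import (Pedigree, inbreeding_coefficients,
                                relationship_matrix)
from methaphen.simulate import simulate_single_trait, simulate_trait_pair
from tests.conftest import random_pedigree, recovery_config


class TestAInverse:
    def test_unrelated_founders_identity(self):
        ped = Pedigree(((1, 0, 0), (2, 0, 0)))
        assert np.allclose(build_a_inverse(ped).matrix.toarray(), np.eye(2))
        assert np.allclose(relationship_matrix(ped), np.eye(2))

    def test_trio(self):
        ped = Pedigree(((1, 0, 0), (2, 0, 0), (3, 1, 2)))
        expected = np.array([[1.5, 0.5, -1.0], [0.5, 1.5, -1.0], [-1.0, -1.0, 2.0]])
        assert np.allclose(build_a_inverse(ped).matrix.toarray(), expected)
        a = relationship_matrix(ped)
        assert np.allclose(a, [[1, 0, 0.5], [0, 1, 0.5], [0.5, 0.5, 1]])

    def test_full_sibs_and_inbred_offspring(self):
        ped = Pedigree(((1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 2), (5, 3, 4)))
        a = relationship_matrix(ped)
        assert a[2, 3] == pytest.approx(0.5)
        f = inbreeding_coefficients(ped)
        assert f[4] == pytest.approx(0.25)
        ai = build_a_inverse(ped)
        assert ai.inbreeding[4] == pytest.approx(0.25)
        assert np.allclose(ai.matrix.toarray(), np.linalg.inv(a), atol=1e-10)

    def test_matches_dense_inverse_on_random_pedigrees(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 51))
            ped = Pedigree(random_pedigree(rng, n=n, n_founders=max(2, n // 6)))
            a = relationship_matrix(ped)
            ainv = build_a_inverse(ped).matrix.toarray()
            assert np.abs(ainv - np.linalg.inv(a)).max() < 1e-8

    def test_cyclic_pedigree_rejected(self):
        with pytest.raises(ValueError):
            Pedigree(((1, 0, 0), (2, 3, 1), (3, 2, 0)))


class TestPosteriorSummaries:
    def test_constant_samples(self):
        s = posterior_summaries(np.full(200, 5.0))
        assert s.mean == 5.0
        assert (s.hpd95_low, s.hpd95_high) == (5.0, 5.0)
        assert s.sign_probability == 1.0 and s.relevant

    def test_symmetric_coin(self):
        draws = np.tile([1.0, -1.0], 500)
        s = posterior_summaries(draws)
        assert s.sign_probability == pytest.approx(0.5, abs=0.01)
        assert not s.relevant

    def test_normal_hpd_matches_quantiles(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal(10_000) + 2.0
        s = posterior_summaries(draws)
        lo, hi = stats.norm.interval(0.95, loc=2.0, scale=1.0)
        assert s.hpd95_low == pytest.approx(lo, abs=0.1)
        assert s.hpd95_high == pytest.approx(hi, abs=0.1)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            posterior_summaries(np.ones(50))


class TestVarianceFunctionals:
    def test_heritability_constant_draws(self):
        d = PosteriorDraws.from_variances(np.full(200, 0.114), np.full(200, 0.9),
                                          np.full(200, 0.367))
        assert heritability(d).mean == pytest.approx(0.2370, abs=5e-5)

    def test_heritability_noiseless_bound(self):
        d = PosteriorDraws.from_variances(np.full(200, 1.0), np.full(200, 1.0),
                                          np.full(200, 0.0))
        assert heritability(d).mean == 1.0

    def test_heritability_reference_daily_production(self):
        d = PosteriorDraws.from_variances(np.full(200, 786.0), np.full(200, 4679.0),
                                          np.full(200, 4762.0))
        assert heritability(d).mean == pytest.approx(0.1417, abs=5e-5)

    def test_herd_fraction_trivial(self):
        one = np.full(200, 1.0)
        zero = np.zeros(200)
        assert herd_fraction(PosteriorDraws.from_variances(zero, one, zero)).mean == 1.0
        d = PosteriorDraws.from_variances(one, one, 2 * one)
        assert herd_fraction(d).mean == pytest.approx(0.25)

    def test_herd_fraction_survey_magnitudes(self):
        d = PosteriorDraws.from_variances(np.full(200, 0.204), np.full(200, 1.819),
                                          np.full(200, 0.539))
        assert herd_fraction(d).mean == pytest.approx(0.7100, abs=5e-5)

    def test_correlation_trivial_cases(self):
        n = 200
        g_diag = np.tile(np.diag([1.0, 2.0]), (n, 1, 1))
        g_unit = np.tile(np.ones((2, 2)), (n, 1, 1))
        h = np.tile(np.diag([1.0, 1.0]), (n, 1, 1))
        d1 = PosteriorDraws(g0=g_diag, h0=h, r0=h, traits=("a", "b"))
        assert component_correlations(d1)["r_G"].mean == pytest.approx(0.0)
        d2 = PosteriorDraws(g0=g_unit, h0=h, r0=h, traits=("a", "b"))
        assert component_correlations(d2)["r_G"].mean == pytest.approx(1.0)


class TestGibbsUnivariate:
    def test_constant_response_rejected(self, recovery_pedigree):
        ped, ainv = recovery_pedigree
        cfg = recovery_config()
        pheno, _ = simulate_single_trait(ped, cfg, 0.2, 1.8, 0.5)
        pheno["y"] = 1.0
        spec = ModelSpec(iterations=200, burn_in=100, thin=1)
        with pytest.raises(ValueError):
            gibbs_univariate(pheno["y"].to_numpy(), pheno, spec, ainv)

    def test_unknown_animal_rejected(self, recovery_pedigree):
        ped, ainv = recovery_pedigree
        cfg = recovery_config()
        pheno, _ = simulate_single_trait(ped, cfg, 0.2, 1.8, 0.5)
        pheno.loc[0, "cow_id"] = 10 ** 7
        spec = ModelSpec(iterations=200, burn_in=100, thin=1)
        with pytest.raises(ValueError):
            gibbs_univariate(pheno["y"].to_numpy(), pheno, spec, ainv)

    def test_bad_chain_settings_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            ModelSpec(thin=0)

    def test_null_additive_variance_recovered(self, recovery_pedigree):
        ped, ainv = recovery_pedigree
        cfg = recovery_config(seed=77)
        pheno, _ = simulate_single_trait(ped, cfg, 0.0, 1.8, 0.7)
        spec = ModelSpec(iterations=4000, burn_in=1000, thin=5, seed=3)
        draws = gibbs_univariate(pheno["y"].to_numpy(), pheno, spec, ainv)
        assert heritability(draws).mean < 0.10

    def test_flat_prior_variance_accounting(self):
        # founders-only, one herd: total posterior variance should approach
        # the frequentist residual mean square of the fixed-effects-only fit
        from methaphen.simulate import SimulationConfig, simulate_pedigree
        cfg = SimulationConfig(n_herds=1, cows_per_herd=400, n_founders=400,
                               n_generations=1, n_sires_per_gen=1,
                               n_dams_per_gen=1, seed=5)
        ped = simulate_pedigree(cfg)
        ainv = build_a_inverse(ped)
        pheno, _ = simulate_single_trait(ped, cfg, 0.3, 0.0, 0.7)
        spec = ModelSpec(iterations=4000, burn_in=1000, thin=5, seed=1)
        draws = gibbs_univariate(pheno["y"].to_numpy(), pheno, spec, ainv)
        y = pheno["y"].to_numpy()
        total = (draws.var_additive() + draws.var_residual()).mean()
        assert total == pytest.approx(np.var(y, ddof=1), rel=0.25)

    @pytest.mark.parametrize("h2_true", [0.1, 0.2, 0.3])
    @pytest.mark.parametrize("h_herd_true", [0.4, 0.6])
    def test_recovery_grid_bias(self, recovery_pedigree, h2_true, h_herd_true):
        ped, ainv = recovery_pedigree
        var_h = h_herd_true
        var_a = h2_true * (1 - h_herd_true)
        var_e = (1 - h2_true) * (1 - h_herd_true)
        ests = []
        for seed in range(10):
            cfg = recovery_config(seed=1000 + 17 * seed)
            pheno, _ = simulate_single_trait(ped, cfg, var_a, var_h, var_e)
            spec = ModelSpec(iterations=5000, burn_in=1250, thin=5, seed=seed)
            draws = gibbs_univariate(pheno["y"].to_numpy(), pheno, spec, ainv)
            ests.append(heritability(draws).mean)
        assert abs(np.mean(ests) - h2_true) <= 0.05

    def test_chain_length_robustness(self, recovery_pedigree):
        ped, ainv = recovery_pedigree
        cfg = recovery_config(seed=31)
        pheno, _ = simulate_single_trait(ped, cfg, 0.2, 1.8, 0.5)
        y = pheno["y"].to_numpy()
        short = gibbs_univariate(y, pheno, ModelSpec(iterations=4000, burn_in=1000,
                                                     thin=5, seed=2), ainv)
        long = gibbs_univariate(y, pheno, ModelSpec(iterations=8000, burn_in=1000,
                                                    thin=5, seed=2), ainv)
        h_short, h_long = heritability(short), heritability(long)
        mcse = h_short.draws.std() / np.sqrt(len(h_short.draws))
        # generous allowance for autocorrelation in the chain
        assert abs(h_short.mean - h_long.mean) < max(10 * mcse, 0.03)


class TestGibbsBivariate:
    def test_self_correlation_limit(self, recovery_pedigree):
        ped, ainv = recovery_pedigree
        cfg = recovery_config(seed=55)
        pheno, _ = simulate_single_trait(ped, cfg, 0.4, 1.0, 0.6)
        rng = np.random.default_rng(1)
        pheno["y1"] = pheno["y"]
        pheno["y2"] = pheno["y"] + rng.standard_normal(len(pheno)) * 0.05
        spec = ModelSpec(traits=("y1", "y2"), iterations=3000, burn_in=1000,
                         thin=5, seed=4)
        draws = gibbs_bivariate(pheno["y1"].to_numpy(), pheno["y2"].to_numpy(),
                                pheno, spec, ainv)
        assert component_correlations(draws)["r_G"].mean > 0.95

    def test_missing_records_handled(self, recovery_pedigree):
        ped, ainv = recovery_pedigree
        cfg = recovery_config(seed=91)
        pheno, _ = simulate_trait_pair(ped, cfg, 0.3, 1.0, 0.7,
                                       genetic_correlation=0.6)
        y2 = pheno["y2"].to_numpy().copy()
        y2[::7] = np.nan
        spec = ModelSpec(traits=("y1", "y2"), iterations=2500, burn_in=800,
                         thin=5, seed=6)
        draws = gibbs_bivariate(pheno["y1"].to_numpy(), y2, pheno, spec, ainv)
        corr = component_correlations(draws)
        assert -1 <= corr["r_G"].mean <= 1
        assert np.all(np.isfinite(draws.g0))

    def test_null_genetic_correlation_rarely_relevant(self, recovery_pedigree):
        ped, ainv = recovery_pedigree
        flags = []
        for seed in range(10):
            cfg = recovery_config(seed=400 + seed)
            pheno, _ = simulate_trait_pair(ped, cfg, 0.3, 1.0, 0.7,
                                           genetic_correlation=0.0)
            spec = ModelSpec(traits=("y1", "y2"), iterations=3000, burn_in=1000,
                             thin=5, seed=seed)
            draws = gibbs_bivariate(pheno["y1"].to_numpy(), pheno["y2"].to_numpy(),
                                    pheno, spec, ainv)
            flags.append(component_correlations(draws)["r_G"].relevant)
        assert sum(flags) <= 2

    def test_retained_draws_positive_definite(self, recovery_pedigree):
        ped, ainv = recovery_pedigree
        cfg = recovery_config(seed=17)
        pheno, _ = simulate_trait_pair(ped, cfg, 0.3, 1.0, 0.7,
                                       genetic_correlation=0.5)
        spec = ModelSpec(traits=("y1", "y2"), iterations=2000, burn_in=500,
                         thin=5, seed=8)
        draws = gibbs_bivariate(pheno["y1"].to_numpy(), pheno["y2"].to_numpy(),
                                pheno, spec, ainv)
        for mats in (draws.g0, draws.h0, draws.r0):
            eig = np.linalg.eigvalsh(mats)
            assert np.all(eig > 0)
        corr = component_correlations(draws)
        for s in corr.values():
            assert -1 <= s.mean <= 1
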