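import numpy as np
import pytest
from scipy import stats

from popthreat.model import ModelSpec, ThreatTrendModel, noncentered_transform
from popthreat.simulate import GeneratorConfig, generate


class TestNoncenteredTransform:
    def test_zero_z_gives_zero_slopes(self):
        assert np.allclose(noncentered_transform(np.zeros(4), 2.0), 0.0)

    def test_zero_sigma_gives_zero_slopes(self):
        assert np.allclose(noncentered_transform(np.ones(4), 0.0), 0.0)

    def test_scalar_scaling(self):
        assert noncentered_transform(np.array([1.5]), 2.0)[0] == pytest.approx(3.0)

    def test_correlated_transform_uses_cholesky(self):
        chol = np.array([[1.0, 0.0], [0.5, 0.8]])
        z = np.array([1.0, 1.0])
        assert np.allclose(noncentered_transform(z, 2.0, chol), 2.0 * chol @ z)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            noncentered_transform(np.ones(3), 1.0, np.eye(2))

    def test_prior_sample_equivalence(self):
        """Noncentered r = z*sigma with z~N(0,1), sigma~Exp(1) matches the
        centered r|sigma ~ N(0, sigma) marginal (two-sample KS at alpha=0.01)."""
        rng = np.random.default_rng(42)
        n = 100_000
        sigma = rng.exponential(1.0, n)
        noncentered = rng.standard_normal(n) * sigma
        sigma2 = rng.exponential(1.0, n)
        centered = rng.normal(0.0, sigma2)
        p = stats.ks_2samp(noncentered, centered).pvalue
        assert p > 0.01


def _toy_model(seed=4, n_species=3, pops=2, ar1=True):
    cfg = GeneratorConfig(
        n_species=n_species,
        populations_per_species=pops,
        n_sites=4,
        span_range=(10, 14),
        missing_rate=0.2,
        seed=seed,
    )
    series, _ = generate(cfg)
    return ThreatTrendModel(series, ar1_enabled=ar1)


def _random_params(model, rng):
    return {
        "beta": rng.normal(0, 0.3, model.n_fixed),
        "z_species": rng.standard_normal(len(model.species_ids)),
        "z_population": rng.standard_normal(len(model.population_ids)),
        "z_site": rng.standard_normal(len(model.site_ids)),
        "sigma": 0.4,
        "rho": 0.25,
        "sigma_species": 0.05,
        "sigma_population": 0.03,
        "sigma_site": 0.02,
    }


def brute_force_logdensity(model, params):
    """Independent evaluation: explicit per-observation loop building mu with
    the lagged residual, summing Normal log densities."""
    beta = np.asarray(params["beta"])
    sig_s, sig_p, sig_l = (
        params["sigma_species"],
        params["sigma_population"],
        params["sigma_site"],
    )
    r_s = sig_s * np.asarray(params["z_species"])
    r_p = sig_p * np.asarray(params["z_population"])
    r_l = sig_l * (model.proximity.cholesky @ np.asarray(params["z_site"]))
    total = 0.0
    row = 0
    for j, prep in enumerate(model.prepared):
        slope = (
            r_s[model.species_of_population[j]]
            + r_p[j]
            + r_l[model.site_of_population[j]]
        )
        eps_prev = 0.0
        for t, y in zip(prep.centered_year, prep.centered_log_abundance):
            m = float(model.design.matrix[row] @ beta) + slope * t
            mu = m + params["rho"] * eps_prev
            total += stats.norm.logpdf(y, mu, params["sigma"])
            eps_prev = y - m
            row += 1
    return total


class TestLikelihoodOracle:
    def test_matches_brute_force_to_1e8(self):
        model = _toy_model()
        rng = np.random.default_rng(0)
        for _ in range(3):
            params = _random_params(model, rng)
            assert model.loglikelihood(params) == pytest.approx(
                brute_force_logdensity(model, params), abs=1e-8
            )

    def test_logposterior_adds_priors(self):
        model = _toy_model()
        params = _random_params(model, np.random.default_rng(1))
        lp = model.logposterior(params) - model.loglikelihood(params)
        expected = (
            stats.norm.logpdf(params["beta"], 0, 1).sum()
            + stats.norm.logpdf(params["z_species"], 0, 1).sum()
            + stats.norm.logpdf(params["z_population"], 0, 1).sum()
            + stats.norm.logpdf(params["z_site"], 0, 1).sum()
            + sum(
                stats.expon.logpdf(params[k])
                for k in ("sigma", "sigma_species", "sigma_population", "sigma_site")
            )
            + stats.norm.logpdf(params["rho"], 0, 0.25)
        )
        assert lp == pytest.approx(expected, abs=1e-8)

    def test_permutation_invariance_of_input_order(self):
        """Shuffling the order of the input series leaves the log density
        unchanged (per-series lag structure is rebuilt internally)."""
        cfg = GeneratorConfig(
            n_species=3, populations_per_species=2, n_sites=4, seed=9
        )
        series, _ = generate(cfg)
        m1 = ThreatTrendModel(series)
        rng = np.random.default_rng(2)
        order = rng.permutation(len(series))
        m2 = ThreatTrendModel([series[i] for i in order])

        params = _random_params(m1, rng)
        # remap population-indexed parameters to the permuted ordering
        params2 = dict(params)
        pop_map = [m2.population_ids.index(p) for p in m1.population_ids]
        z2 = np.empty_like(params["z_population"])
        z2[pop_map] = params["z_population"]
        params2["z_population"] = z2
        sp_map = [m2.species_ids.index(s) for s in m1.species_ids]
        zs2 = np.empty_like(params["z_species"])
        zs2[sp_map] = params["z_species"]
        params2["z_species"] = zs2
        # site slopes: express the same r_l in the permuted site basis
        r_l = m1.proximity.cholesky @ params["z_site"]
        site_map = [m2.site_ids.index(s) for s in m1.site_ids]
        r_l2 = np.empty_like(r_l)
        r_l2[site_map] = r_l
        params2["z_site"] = np.linalg.solve(m2.proximity.cholesky, r_l2)

        assert m1.loglikelihood(params) == pytest.approx(
            m2.loglikelihood(params2), abs=1e-6
        )


class TestFitMechanics:
    def test_seed_determinism(self):
        model = _toy_model(seed=6)
        spec = ModelSpec(chains=2, iterations=120, warmup=60, seed=77)
        d1 = model.fit(spec).draws
        d2 = model.fit(spec).draws
        assert np.array_equal(d1.beta, d2.beta)
        assert np.array_equal(d1.rho, d2.rho)

    def test_different_seeds_differ(self):
        model = _toy_model(seed=6)
        d1 = model.fit(chains=1, iterations=120, warmup=60, seed=1).draws
        d2 = model.fit(chains=1, iterations=120, warmup=60, seed=2).draws
        assert not np.array_equal(d1.beta, d2.beta)

    def test_draw_count_and_labels(self):
        model = _toy_model(seed=6)
        res = model.fit(chains=2, iterations=100, warmup=40, seed=0)
        assert res.draws.n_chains == 2
        assert res.draws.n_draws == 60
        assert res.draws.beta.shape[2] == model.n_fixed
        assert res.draws.beta_labels == model.design.column_labels

    def test_ar1_disabled_fixes_rho_at_zero(self):
        model = _toy_model(seed=6, ar1=False)
        res = model.fit(chains=1, iterations=100, warmup=40, seed=0)
        assert np.all(res.draws.rho == 0.0)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(chains=2, iterations=100, warmup=100)

    def test_json_round_trip(self, tmp_path):
        from popthreat.draws import PosteriorDraws

        model = _toy_model(seed=6)
        res = model.fit(chains=1, iterations=80, warmup=40, seed=0)
        path = tmp_path / "draws.json"
        res.save(path)
        back = PosteriorDraws.from_json(path)
        assert np.allclose(back.beta, res.draws.beta)
        assert back.beta_labels == res.draws.beta_labels
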