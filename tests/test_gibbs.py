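"""The Gibbs engine against conjugate closed forms and grid oracles."""

import numpy as np
import pandas as pd
import pytest

from priorpool import (
    MCMCConfig,
    MixtureDensity,
    NormalDensity,
    PriorAssignment,
    build_model_spec,
    fit_gibbs,
    indirect_effects,
    pool_imputations,
)
from priorpool.gibbs import PosteriorDraws
from priorpool.pathmodel import Equation, PathModelSpec


class TestConjugateOracle:
    def test_posterior_matches_closed_form(self, single_equation_spec, toy_regression):
        """y = bx + e with fixed residual variance and a N(0,10) prior has an
        exactly normal posterior: precision x'x/s2 + 1/100."""
        x = toy_regression["x"].to_numpy()
        y = toy_regression["y"].to_numpy()
        priors = PriorAssignment({"beta": NormalDensity(0.0, 10.0)})
        cfg = MCMCConfig(chains=3, iterations=6_000, warmup=1_000)
        draws = fit_gibbs(
            toy_regression, single_equation_spec, priors, cfg, seed=5,
            fixed_residual_variance={"y": 1.0},
        )
        lam = x @ x + 1.0 / 100.0
        mean_cf = (x @ y) / lam
        b = draws.pooled("beta")
        mcse = np.sqrt(1.0 / lam / len(b)) * 3
        assert b.mean() == pytest.approx(mean_cf, abs=max(5 * mcse, 5e-3))
        assert b.var(ddof=1) == pytest.approx(1.0 / lam, rel=0.1)

    def test_dogmatic_prior_pins_the_posterior(self, single_equation_spec, toy_regression):
        priors = PriorAssignment({"beta": NormalDensity(0.3, 1e-8)})
        cfg = MCMCConfig(chains=2, iterations=500, warmup=100)
        draws = fit_gibbs(
            toy_regression, single_equation_spec, priors, cfg, seed=5,
            fixed_residual_variance={"y": 1.0},
        )
        assert np.allclose(draws.pooled("beta"), 0.3, atol=1e-6)

    def test_mixture_prior_matches_grid_posterior(self, single_equation_spec):
        """With a two-component mixture prior the posterior is bimodal; the
        sampled CDF must match likelihood x prior on a fine grid."""
        rng = np.random.default_rng(8)
        n = 25
        x = rng.standard_normal(n)
        y = 0.05 * x + rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "y": y})
        prior = MixtureDensity(
            (NormalDensity(-0.35, 0.08), NormalDensity(0.45, 0.12))
        )
        priors = PriorAssignment({"beta": prior})
        cfg = MCMCConfig(chains=3, iterations=45_000, warmup=5_000)
        draws = fit_gibbs(
            df, single_equation_spec, priors, cfg, seed=10,
            fixed_residual_variance={"y": 1.0},
        )
        b = np.sort(draws.pooled("beta"))

        grid = np.linspace(-1.5, 1.5, 12_001)
        loglik = grid * (x @ y) - 0.5 * grid**2 * (x @ x)
        post = np.exp(loglik - loglik.max()) * prior.pdf(grid)
        post /= np.trapezoid(post, grid)
        cdf_grid = np.cumsum(post)
        cdf_grid /= cdf_grid[-1]
        cdf_at_draws = np.interp(b, grid, cdf_grid)
        ecdf = (np.arange(1, len(b) + 1) - 0.5) / len(b)
        assert np.max(np.abs(cdf_at_draws - ecdf)) < 0.01
        # and both posterior modes are actually visited
        assert (b < 0).mean() > 0.05 and (b > 0).mean() > 0.05


@pytest.fixture(scope="module")
def known_model_data():
    """n = 5,000 dyads simulated straight from Model A's equations."""
    rng = np.random.default_rng(100)
    n = 5_000
    true = {
        "MPonMint": -0.25, "MPonAint": -0.15,
        "APonMint": -0.12, "APonAint": -0.16,
        "MintonMP": -0.10, "MintonAP": 0.05, "MintonMint": 0.50,
        "AintonMP": -0.08, "AintonAP": -0.05, "AintonAint": 0.45,
    }
    mint1 = rng.standard_normal(n)
    aint1 = rng.standard_normal(n)
    mp2 = true["MPonMint"] * mint1 + true["MPonAint"] * aint1 + rng.standard_normal(n)
    ap2 = true["APonMint"] * mint1 + true["APonAint"] * aint1 + rng.standard_normal(n)
    mint3 = (true["MintonMP"] * mp2 + true["MintonAP"] * ap2
             + true["MintonMint"] * mint1 + rng.standard_normal(n))
    aint3 = (true["AintonMP"] * mp2 + true["AintonAP"] * ap2
             + true["AintonAint"] * aint1 + rng.standard_normal(n))
    data = pd.DataFrame(
        {"Mint1": mint1, "Aint1": aint1, "MP2": mp2, "AP2": ap2,
         "Mint3": mint3, "Aint3": aint3}
    )
    return data, true


@pytest.fixture(scope="module")
def diffuse_fit(known_model_data):
    data, _ = known_model_data
    spec = build_model_spec("A")
    priors = PriorAssignment.diffuse(spec.coefficient_names)
    cfg = MCMCConfig(chains=2, iterations=1_200, warmup=400)
    return fit_gibbs(data, spec, priors, cfg, seed=17)


class TestRecovery:
    def test_posterior_means_recover_generating_coefficients(
        self, known_model_data, diffuse_fit
    ):
        _, true = known_model_data
        for name, value in true.items():
            b = diffuse_fit.pooled(name)
            assert abs(b.mean() - value) < 3 * b.std(ddof=1), name

    def test_diffuse_posterior_agrees_with_ols(self, known_model_data, diffuse_fit):
        data, _ = known_model_data
        spec = build_model_spec("A")
        for eq in spec.equations:
            X = np.column_stack(
                [np.ones(len(data))] + [data[p].to_numpy() for p in eq.predictors]
            )
            ols = np.linalg.lstsq(X, data[eq.response].to_numpy(), rcond=None)[0]
            for coef_hat, name in zip(ols[1:], eq.coef_names):
                assert diffuse_fit.pooled(name).mean() == pytest.approx(
                    coef_hat, abs=0.02
                ), name


class TestBookkeeping:
    def test_identical_seeds_reproduce_bit_identically(
        self, single_equation_spec, toy_regression
    ):
        priors = PriorAssignment({"beta": NormalDensity(0, 10)})
        cfg = MCMCConfig(chains=2, iterations=300, warmup=100)
        d1 = fit_gibbs(toy_regression, single_equation_spec, priors, cfg, seed=4)
        d2 = fit_gibbs(toy_regression, single_equation_spec, priors, cfg, seed=4)
        assert np.array_equal(d1.draws["beta"], d2.draws["beta"])
        d3 = fit_gibbs(toy_regression, single_equation_spec, priors, cfg, seed=5)
        assert not np.array_equal(d1.draws["beta"], d3.draws["beta"])

    def test_kept_draw_counts_match_config(self, small_dyads):
        from priorpool import standardize

        spec = build_model_spec("A")
        priors = PriorAssignment.diffuse(spec.coefficient_names)
        cfg = MCMCConfig(chains=2, iterations=250, warmup=100)
        data = standardize(small_dyads)
        draws = fit_gibbs([data, data], spec, priors, cfg, seed=3)
        for name in spec.coefficient_names:
            assert draws.draws[name].shape == (2, 2, 150)
        assert len(draws.pooled(name)) == 2 * 2 * 150

    def test_incomplete_dataset_rejected(self, small_dyads):
        spec = build_model_spec("A")
        priors = PriorAssignment.diffuse(spec.coefficient_names)
        holed = small_dyads.copy()
        holed.loc[0, "MP2"] = np.nan
        with pytest.raises(ValueError, match="complete"):
            fit_gibbs(holed, spec, priors, MCMCConfig(2, 100, 10), seed=1)


class TestPoolImputations:
    def _draws(self, value, cfg):
        arr = np.full((1, cfg.chains, cfg.kept), float(value))
        return PosteriorDraws(draws={"beta": arr}, config=cfg)

    def test_concatenation_counts(self):
        cfg = MCMCConfig(chains=3, iterations=120, warmup=20)
        pooled = pool_imputations([self._draws(v, cfg) for v in (0.1, 0.2, 0.3)])
        assert pooled.draws["beta"].shape == (3, 3, 100)

    def test_pooled_mean_is_average_of_per_imputation_means(self):
        cfg = MCMCConfig(chains=2, iterations=60, warmup=10)
        pooled = pool_imputations([self._draws(v, cfg) for v in (0.0, 1.0)])
        assert pooled.pooled("beta").mean() == pytest.approx(0.5)

    def test_identical_imputations_preserve_distribution(self):
        cfg = MCMCConfig(chains=2, iterations=60, warmup=10)
        rng = np.random.default_rng(0)
        arr = rng.standard_normal((1, 2, 50))
        d = PosteriorDraws(draws={"beta": arr}, config=cfg)
        pooled = pool_imputations([d, d, d])
        assert pooled.pooled("beta").mean() == pytest.approx(arr.mean())
        assert pooled.pooled("beta").var() == pytest.approx(arr.var())

    def test_mismatched_parameters_rejected(self):
        cfg = MCMCConfig(chains=2, iterations=60, warmup=10)
        a = self._draws(0.1, cfg)
        b = PosteriorDraws(
            draws={"gamma": np.zeros((1, 2, 50))}, config=cfg
        )
        with pytest.raises(ValueError):
            pool_imputations([a, b])


class TestIndirectEffects:
    def _degenerate_draws(self, spec, a=0.5, b=0.4):
        cfg = MCMCConfig(chains=2, iterations=110, warmup=10)
        shape = (1, 2, 100)
        draws = {}
        for name in spec.coefficient_names:
            draws[name] = np.full(shape, a if "on" in name and
                                  name.startswith(("MP", "AP", "MN", "AN")) else b)
        return PosteriorDraws(draws=draws, config=cfg)

    def test_constant_product(self):
        spec = build_model_spec("A")
        effects = indirect_effects(self._degenerate_draws(spec), spec)
        for eff in effects:
            assert np.allclose(eff.pooled(), 0.5 * 0.4)

    @pytest.mark.parametrize("label", ["A", "B"])
    def test_eight_effects_with_table_naming(self, label):
        spec = build_model_spec(label)
        effects = indirect_effects(self._degenerate_draws(spec), spec)
        names = {e.name for e in effects}
        assert len(effects) == 8
        med = "MP" if label == "A" else "MN"
        amed = "AP" if label == "A" else "AN"
        expected_cross = {
            f"Aint{med}Mint", f"Aint{amed}Mint", f"Mint{med}Aint", f"Mint{amed}Aint"
        }
        assert expected_cross <= names

    def test_product_moments_for_independent_normal_draws(self):
        spec = build_model_spec("A")
        cfg = MCMCConfig(chains=2, iterations=100_010, warmup=10)
        rng = np.random.default_rng(3)
        shape = (1, 2, 100_000)
        draws = {}
        for name in spec.coefficient_names:
            if name == "MPonMint":
                draws[name] = rng.normal(0.5, 0.1, shape)
            elif name == "AintonMP":
                draws[name] = rng.normal(0.4, 0.1, shape)
            else:
                draws[name] = np.zeros(shape)
        pd_draws = PosteriorDraws(draws=draws, config=cfg)
        eff = {e.name: e for e in indirect_effects(pd_draws, spec)}["AintMPMint"]
        x = eff.pooled()
        assert x.mean() == pytest.approx(0.20, abs=0.005)
        expected_var = 0.5**2 * 0.01 + 0.4**2 * 0.01 + 0.0001
        assert x.var() == pytest.approx(expected_var, rel=0.05)

    def test_missing_component_path_rejected(self):
        spec = build_model_spec("A")
        d = self._degenerate_draws(spec)
        broken = {k: v for k, v in d.draws.items() if k != "MPonMint"}
        with pytest.raises(KeyError, match="MPonMint"):
            indirect_effects(PosteriorDraws(draws=broken, config=d.config), spec)
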