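"""Convergence statistics, shrinkage, HPD, fmi, and prior predictive checks."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from priorpool import (
    NormalDensity,
    PriorAssignment,
    build_model_spec,
    ess,
    fmi,
    hpd,
    hpd_union,
    prior_predictive,
    psr,
    shrinkage,
)
from priorpool.diagnostics import DegenerateDrawsError


def _psr_oracle(chains):
    """Direct formula evaluation on explicit half-chains."""
    halves = []
    for ch in chains:
        n = len(ch)
        halves.append(ch[: n // 2])
        halves.append(ch[n - n // 2:])
    halves = np.asarray(halves, dtype=float)
    m, n = halves.shape
    W = halves.var(axis=1, ddof=1).mean()
    B = n * halves.mean(axis=1).var(ddof=1)
    return math.sqrt(((n - 1) / n * W + B / n) / W)


class TestPSR:
    def test_matches_hand_coded_formula(self):
        chains = np.array([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        assert psr(chains) == pytest.approx(_psr_oracle(chains), abs=1e-12)

    def test_matches_formula_on_random_chains(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((3, 50))
        assert psr(chains) == pytest.approx(_psr_oracle(chains), abs=1e-12)

    def test_iid_chains_converge(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((2, 10_000))
        assert psr(chains) < 1.01

    def test_disjoint_support_flags_nonconvergence(self):
        rng = np.random.default_rng(2)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(50, 1, 500)])
        assert psr(chains) > 1.1

    def test_single_chain_is_split_in_half(self):
        rng = np.random.default_rng(3)
        draws = rng.standard_normal(2_000)
        assert psr(draws) == pytest.approx(_psr_oracle([draws]), abs=1e-12)

    def test_degenerate_chain_rejected(self):
        with pytest.raises(DegenerateDrawsError):
            psr(np.ones((2, 100)))

    def test_agrees_with_reference_implementation(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(12)
        chains = rng.standard_normal((3, 400)) + np.array([[0.0], [0.1], [0.2]])
        reference = float(az.rhat(az.convert_to_dataset(chains), method="split").x.values)
        assert psr(chains) == pytest.approx(reference, abs=1e-6)


class TestESS:
    def test_iid_draws_near_total(self):
        rng = np.random.default_rng(4)
        value = ess(rng.standard_normal(10_000))
        assert 8_000 <= value <= 12_000

    def test_ar1_closed_form(self):
        rho, n = 0.9, 50_000
        rng = np.random.default_rng(5)
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * math.sqrt(1 - rho**2)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t]
        expected = n * (1 - rho) / (1 + rho)
        assert ess(x) == pytest.approx(expected, rel=0.25)

    def test_never_exceeds_total_draws(self):
        rng = np.random.default_rng(6)
        chains = rng.standard_normal((3, 500))
        assert ess(chains) <= 1_500

    def test_constant_draws_signalled(self):
        with pytest.raises(DegenerateDrawsError):
            ess(np.full(1_000, 2.5))

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            ess(np.arange(50, dtype=float))

    def test_matches_plain_loop_formula_oracle(self):
        """FFT-based implementation vs a naive O(n^2) evaluation of the same
        between/within autocorrelation estimator with Geyer-pair truncation."""
        rng = np.random.default_rng(13)
        raw = rng.standard_normal((2, 300))
        chains = raw + 0.5 * np.roll(raw, 1, axis=1)  # mildly autocorrelated
        m, n = chains.shape
        W = chains.var(axis=1, ddof=1).mean()
        B = n * chains.mean(axis=1).var(ddof=1)
        var_plus = (n - 1) / n * W + B / n
        acov = np.zeros(n)
        for c in range(m):
            x = chains[c] - chains[c].mean()
            for t in range(n):
                acov[t] += np.dot(x[: n - t], x[t:]) / n
        acov /= m
        rho = 1.0 - (W - acov) / var_plus
        rho[0] = 1.0
        tau, t = 0.0, 1
        while t + 1 < n:
            pair = rho[t] + rho[t + 1]
            if pair <= 0:
                break
            tau += pair
            t += 2
        expected = min(m * n, m * n / (1 + 2 * tau))
        assert ess(chains) == pytest.approx(expected, abs=1e-6)


class TestShrinkage:
    def test_no_contraction(self):
        assert shrinkage(2.0, 2.0) == 0.0

    def test_full_contraction(self):
        assert shrinkage(2.0, 0.0) == 1.0

    def test_diffuse_prior_arithmetic(self):
        assert shrinkage(1e4, 1.0) == pytest.approx(0.9999)

    def test_posterior_wider_than_prior_goes_negative(self):
        assert shrinkage(1.0, 1.1) == pytest.approx(-0.1)

    def test_nonpositive_prior_variance_rejected(self):
        with pytest.raises(ValueError):
            shrinkage(0.0, 1.0)

    @given(st.floats(1e-6, 1e6))
    def test_identities_for_all_positive_variances(self, v):
        assert shrinkage(v, v) == 0.0
        assert shrinkage(v, 0.0) == 1.0


class TestHPD:
    def test_point_mass_zero_width(self):
        iv = hpd(np.full(500, 1.5))
        assert iv.lower == iv.upper == 1.5

    def test_uniform_width(self):
        rng = np.random.default_rng(7)
        iv = hpd(rng.uniform(0, 1, 1_000_000), mass=0.95)
        assert iv.width == pytest.approx(0.95, abs=0.01)

    def test_standard_normal_quantiles(self):
        rng = np.random.default_rng(8)
        iv = hpd(rng.standard_normal(1_000_000), mass=0.95)
        assert iv.lower == pytest.approx(-1.96, abs=0.02)
        assert iv.upper == pytest.approx(1.96, abs=0.02)

    def test_agrees_with_reference_implementation(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(9)
        draws = rng.gamma(2.0, 1.0, 200_000)
        ours = hpd(draws, 0.9)
        lo, hi = az.hdi(draws, hdi_prob=0.9)
        assert ours.lower == pytest.approx(lo, abs=0.01)
        assert ours.upper == pytest.approx(hi, abs=0.01)

    def test_symmetric_unimodal_matches_equal_tails(self):
        rng = np.random.default_rng(10)
        draws = rng.standard_normal(500_000)
        iv = hpd(draws, 0.8)
        lo, hi = np.quantile(draws, [0.1, 0.9])
        assert iv.lower == pytest.approx(lo, abs=0.02)
        assert iv.upper == pytest.approx(hi, abs=0.02)

    def test_invalid_mass_rejected(self):
        with pytest.raises(ValueError):
            hpd(np.arange(200, dtype=float), mass=1.5)

    def test_union_variant_separates_bimodal_draws(self):
        rng = np.random.default_rng(11)
        draws = np.concatenate(
            [rng.normal(-3, 0.2, 50_000), rng.normal(3, 0.2, 50_000)]
        )
        pieces = hpd_union(draws, 0.9)
        assert len(pieces) >= 2
        assert not any(p.contains(0.0) for p in pieces)


class TestFMI:
    def test_identical_estimates_no_missing_information(self):
        assert fmi([(0.5, 0.01)] * 20) == 0.0

    def test_rubin_formula_arithmetic(self):
        # m = 20 pairs engineered so B equals U-bar exactly
        m, U = 20, 0.04
        means = np.linspace(-1, 1, m)
        means *= math.sqrt(U / means.var(ddof=1))
        pairs = [(mu, U) for mu in means]
        expected = 1.05 * U / (U + 1.05 * U)
        assert fmi(pairs) == pytest.approx(expected, abs=1e-12)

    def test_strictly_increasing_in_between_variance(self):
        U = 0.5
        values = []
        for scale in (0.1, 0.5, 1.0, 2.0):
            means = np.array([-1.0, 0.0, 1.0]) * scale
            values.append(fmi([(mu, U) for mu in means]))
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_single_imputation_rejected(self):
        with pytest.raises(ValueError):
            fmi([(0.5, 0.01)])


class TestPriorPredictive:
    def test_point_mass_priors_give_clt_spread(self):
        spec = build_model_spec("A")
        tight = PriorAssignment(
            {n: NormalDensity(0.0, 1e-12) for n in spec.parameter_names}
        )
        n = 400
        summ = prior_predictive(spec, tight, n=n, n_draws=800, seed=0)
        for resp in ("MP2", "AP2"):
            means = summ.pairs[resp][:, 0]
            assert abs(means.mean()) < 3 / math.sqrt(n * 800)
            assert means.std(ddof=1) == pytest.approx(1 / math.sqrt(n), rel=0.15)

    def test_default_priors_blow_up_predictive_spread(self):
        spec = build_model_spec("A")
        informative = PriorAssignment(
            {n: NormalDensity(0.0, 0.2) for n in spec.coefficient_names}
        )
        diffuse = PriorAssignment.diffuse(spec.coefficient_names, sd=100.0)
        kw = dict(n=102, n_draws=400, seed=1)
        inf = prior_predictive(spec, informative, **kw)
        dif = prior_predictive(spec, diffuse, **kw)
        iqr = lambda a: np.subtract(*np.percentile(a, [75, 25]))
        ratio = iqr(dif.pairs["Aint3"][:, 0]) / iqr(inf.pairs["Aint3"][:, 0])
        assert ratio > 10

    def test_informative_predictive_centers_on_zero(self):
        spec = build_model_spec("A")
        informative = PriorAssignment(
            {n: NormalDensity(0.0, 0.2) for n in spec.coefficient_names}
        )
        summ = prior_predictive(spec, informative, n=102, n_draws=500, seed=2)
        for resp in summ.pairs:
            means = summ.pairs[resp][:, 0]
            assert abs(np.median(means)) < 2 * means.std(ddof=1)

    def test_draw_bookkeeping(self):
        spec = build_model_spec("B")
        priors = PriorAssignment()
        summ = prior_predictive(spec, priors, n=50, n_draws=500, seed=3)
        assert summ.n_draws == 500
        for resp in ("MN2", "AN2", "Mint3", "Aint3"):
            assert summ.pairs[resp].shape == (500, 2)

    def test_tiny_n_rejected(self):
        spec = build_model_spec("A")
        with pytest.raises(ValueError):
            prior_predictive(spec, PriorAssignment(), n=1, n_draws=10, seed=0)
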