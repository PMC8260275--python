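import math

import numpy as np
import pytest
from scipy.stats import norm, poisson

from multinoise import (
    BinnedDataset,
    MultistageModel,
    NoiseParams,
    SoftplusParams,
    log_likelihood,
    log_likelihood_lnp,
    p_lambda,
    p_y,
    p_z,
    response_pmf,
    simulate_responses,
    softplus_eval,
)
from multinoise.metrics import DiscreteDistribution, jsd

from conftest import random_model


def brute_force_count_prob(m, x, k, n_u=40001, span=10.0):
    """Independent oracle: dense-trapezoid quadrature of the conditionally
    Gaussian count probability over the upstream noise."""
    nl, ns = m.nonlinearity, m.noise
    lo, hi = k - 0.5, k + 0.5
    if k == 0:
        lo = -np.inf
    a = ns.sigma_mult ** 2

    def mass(lam):
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        out = np.zeros_like(lam)
        branches = [(ns.p_down, a * lam + ns.sigma_down ** 2), (1 - ns.p_down, a * lam)]
        for w, var in branches:
            if w == 0:
                continue
            pos = var > 0
            sd = np.sqrt(np.where(pos, var, 1.0))
            cont = norm.cdf((hi - lam) / sd)
            if np.isfinite(lo):
                cont = cont - norm.cdf((lo - lam) / sd)
                ind = (lam <= hi) & (lam > lo)
            else:
                ind = lam <= hi
            out = out + w * np.where(pos, cont, ind.astype(float))
        return out

    if ns.sigma_up == 0:
        return float(mass(float(softplus_eval(nl, x)))[0])
    u = np.linspace(-span * ns.sigma_up, span * ns.sigma_up, n_u)
    dens = norm.pdf(u, scale=ns.sigma_up)
    lam = np.asarray(softplus_eval(nl, x + u))
    return float(np.trapezoid(mass(lam) * dens, u))


def pmf_to_dist(pmf):
    p = pmf.probs.copy()
    p[-1] += pmf.tail_mass
    return DiscreteDistribution(p)


class TestStageDensities:
    def test_p_lambda_delta_limit(self, mixed_model):
        m = mixed_model.with_noise(sigma_up=0.0)
        g = p_lambda(m, 0.7)
        assert g.atom is not None
        assert g.atom[0] == pytest.approx(softplus_eval(m.nonlinearity, 0.7))
        assert g.atom[1] == 1.0

    def test_p_lambda_small_sigma_concentrates(self, mixed_model):
        m = mixed_model.with_noise(sigma_up=1e-3)
        g = p_lambda(m, 0.7)
        assert g.mean() == pytest.approx(softplus_eval(m.nonlinearity, 0.7), abs=1e-4)

    def test_p_lambda_linear_regime_gaussian(self):
        # far in the linear regime the change of variables is affine:
        # P_Lambda ~ N(f(x), (beta1*beta2*sigma_up)^2)
        nl = SoftplusParams(1.5, 2.0, 0.0, 0.0)
        m = MultistageModel(nl, NoiseParams(0.3, 0, 0))
        x = 8.0
        g = p_lambda(m, x)
        mu = float(softplus_eval(nl, x))
        sd = 1.5 * 2.0 * 0.3
        ref = norm.pdf(g.points, mu, sd)
        # agreement up to the residual curvature of the softplus at b2*x+b3 ~ 16
        assert np.max(np.abs(g.values - ref)) < 1e-4 * norm.pdf(0, scale=sd)

    def test_p_lambda_matches_histogram(self):
        nl = SoftplusParams(1.0, 2.0, 0.0, 0.0)
        m = MultistageModel(nl, NoiseParams(0.5, 0, 0))
        g = p_lambda(m, 0.0)
        rng = np.random.default_rng(0)
        lam = softplus_eval(nl, 0.0 + 0.5 * rng.standard_normal(10**6))
        hist_edges = np.linspace(g.points[0], g.points[-1], 200)
        hist, _ = np.histogram(lam, bins=hist_edges, density=True)
        centers = 0.5 * (hist_edges[1:] + hist_edges[:-1])
        dens = np.interp(centers, g.points, g.values)
        widths = np.diff(hist_edges)
        p_emp = hist * widths
        p_th = dens * widths
        p_th = np.append(p_th, max(1 - p_th.sum(), 0))
        p_emp = np.append(p_emp, max(1 - p_emp.sum(), 0))
        d = jsd(DiscreteDistribution(p_emp / p_emp.sum()), DiscreteDistribution(p_th / p_th.sum()))
        assert d < 1e-3

    def test_p_y_identity_when_no_mult_noise(self, mixed_model):
        m = mixed_model.with_noise(sigma_mult=0.0)
        gy = p_y(m, 0.5)
        gl = p_lambda(m, 0.5)
        assert np.array_equal(gy.points, gl.points)
        assert np.array_equal(gy.values, gl.values)

    def test_p_y_single_lambda_gaussian(self):
        # sigma_up = 0, f(x) = 4, sigma_mult^2 = 1.5  ->  P_Y = N(4, 6)
        nl = SoftplusParams(1, 1, -50, 4.0)
        m = MultistageModel(nl, NoiseParams(0.0, math.sqrt(1.5), 0.0))
        g = p_y(m, 0.0)
        ref = norm.pdf(g.points, 4.0, math.sqrt(6.0))
        assert np.max(np.abs(g.values - ref)) < 1e-9

    def test_p_z_pure_shift(self):
        nl = SoftplusParams(1, 1, -50, 2.0)
        m = MultistageModel(nl, NoiseParams(0.0, 0.0, 0.7))
        g = p_z(m, 0.0)
        ref = norm.pdf(g.points, 2.0, 0.7)
        assert np.max(np.abs(g.values - ref)) < 1e-9

    def test_p_z_identity_when_no_down_noise(self, mixed_model):
        m = mixed_model.with_noise(sigma_down=0.0)
        gz = p_z(m, 0.5)
        gy = p_y(m, 0.5)
        assert np.array_equal(gz.points, gy.points)

    @pytest.mark.parametrize("x", [-0.5, 0.3, 1.5])
    def test_normalization_all_stages(self, mixture_model, x):
        for fn in (p_lambda, p_y, p_z):
            g = fn(mixture_model, x)
            assert g.integral() == pytest.approx(1.0, abs=1e-6)

    def test_mixture_blend(self):
        """Mixture p_z is p_down*(P_Y conv N(0,sd^2)) + (1-p_down)*P_Y."""
        nl = SoftplusParams(1.0, 2.0, 0.0, 0.2)
        m = MultistageModel(nl, NoiseParams(0.4, 0.8, 0.5, 0.5, "mixture"))
        g = p_z(m, 0.8)
        m_conv = m.with_noise(p_down=1.0, variant="gaussian")
        m_nov = m.with_noise(sigma_down=0.0, p_down=1.0, variant="gaussian")
        g1 = p_z(m_conv, 0.8)
        g0 = p_z(m_nov, 0.8)
        v1 = np.interp(g.points, g1.points, g1.values)
        v0 = np.interp(g.points, g0.points, g0.values)
        assert np.max(np.abs(g.values - 0.5 * v1 - 0.5 * v0)) < 1e-4


class TestResponsePMF:
    def test_noiseless_point_mass(self):
        m = MultistageModel(SoftplusParams(1, 1, -50, 2.4), NoiseParams(0, 0, 0))
        pmf = response_pmf(m, 0.0)
        assert pmf.probs[2] == pytest.approx(1.0)
        assert pmf.mean() == pytest.approx(2.4, abs=0.5)

    def test_rectified_gaussian_closed_form(self):
        m = MultistageModel(SoftplusParams(1, 1, -50, 0.0), NoiseParams(0, 0, 1.0))
        pmf = response_pmf(m, 0.0)
        assert pmf.probs[0] == pytest.approx(norm.cdf(0.5), abs=1e-6)
        assert pmf.probs[1] == pytest.approx(norm.cdf(1.5) - norm.cdf(0.5), abs=1e-6)

    def test_tail_mass_below_tolerance(self, mixture_model):
        pmf = response_pmf(mixture_model, 1.0)
        assert pmf.tail_mass < 1e-8
        assert pmf.probs.sum() + pmf.tail_mass == pytest.approx(1.0, abs=1e-6)

    def test_matches_simulation(self, mixed_model):
        x = 1.0
        pmf = response_pmf(mixed_model, x)
        sims = simulate_responses(mixed_model, np.full(10**6, x), seed=11)
        emp = DiscreteDistribution.from_counts(sims, support_size=pmf.r_max + 1)
        assert jsd(emp, pmf_to_dist(pmf)) < 1e-3

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        for variant in ("gaussian", "mixture"):
            m = random_model(rng, variant)
            x = rng.uniform(-2, 2)
            pmf = response_pmf(m, x)
            for k in range(min(pmf.r_max, 8) + 1):
                assert pmf.probs[k] == pytest.approx(
                    brute_force_count_prob(m, x, k), abs=1e-7)


class TestLogLikelihood:
    def test_single_bin_closed_form(self):
        m = MultistageModel(SoftplusParams(1, 1, -50, 0.0), NoiseParams(0, 0, 1.0))
        d = BinnedDataset(np.array([0.0]), np.array([0]))
        assert log_likelihood(m, d) == pytest.approx(math.log(norm.cdf(0.5)), abs=1e-9)

    def test_additivity_on_duplication(self, mixture_model, small_dataset):
        ll1 = log_likelihood(mixture_model, small_dataset)
        doubled = BinnedDataset(
            np.concatenate([small_dataset.inputs] * 2),
            np.concatenate([small_dataset.counts] * 2),
        )
        assert log_likelihood(mixture_model, doubled) == pytest.approx(2 * ll1, rel=1e-12)

    @pytest.mark.parametrize("variant", ["gaussian", "mixture"])
    def test_matches_brute_force_quadrature(self, variant):
        rng = np.random.default_rng(17)
        for _ in range(4):
            m = random_model(rng, variant)
            x = rng.uniform(-2, 2, size=20)
            counts = simulate_responses(m, x, seed=int(rng.integers(2**31)))
            d = BinnedDataset(x, counts)
            ll = log_likelihood(m, d)
            ll_ref = sum(
                math.log(max(brute_force_count_prob(m, xv, int(k)), 1e-300))
                for xv, k in zip(x, counts)
            )
            assert ll == pytest.approx(ll_ref, abs=1e-4 * len(x))

    def test_gaussian_equals_mixture_at_pdown_one(self, small_dataset):
        nl = SoftplusParams(1.0, 2.0, 0.0, 0.1)
        mg = MultistageModel(nl, NoiseParams(0.4, 0.9, 0.5, 1.0, "gaussian"))
        mm = MultistageModel(nl, NoiseParams(0.4, 0.9, 0.5, 1.0, "mixture"))
        assert log_likelihood(mg, small_dataset) == pytest.approx(
            log_likelihood(mm, small_dataset), abs=1e-8)

    def test_probability_floor_no_nan(self):
        # an impossible observation under a near-deterministic model
        m = MultistageModel(SoftplusParams(1, 1, -50, 0.0), NoiseParams(0, 0, 1e-6))
        d = BinnedDataset(np.array([0.0]), np.array([50]))
        with pytest.warns(RuntimeWarning):
            ll = log_likelihood(m, d)
        assert np.isfinite(ll)

    def test_history_weight_conditioning(self):
        nl = SoftplusParams(1.0, 1.0, 0.0, 0.5)
        m = MultistageModel(nl, NoiseParams(0.0, 0.0, 1.0), history_weight=0.7)
        x = np.array([0.0, 0.0])
        r = np.array([3, 0])
        d = BinnedDataset(x, r)
        # bin 2's input is shifted by 0.7*3; compute both bins directly
        m_plain = MultistageModel(nl, NoiseParams(0.0, 0.0, 1.0))
        ll_manual = (
            log_likelihood(m_plain, BinnedDataset(np.array([0.0]), np.array([3])))
            + log_likelihood(m_plain, BinnedDataset(np.array([0.7 * 3]), np.array([0])))
        )
        assert log_likelihood(m, d) == pytest.approx(ll_manual, rel=1e-10)


class TestLNP:
    def test_poisson_pointwise(self):
        d0 = BinnedDataset(np.array([0.0]), np.array([0]))
        p1 = SoftplusParams(1, 1, -50, 1.0)  # f == 1
        assert log_likelihood_lnp(p1, d0) == pytest.approx(-1.0)
        d2 = BinnedDataset(np.array([0.0]), np.array([2]))
        p2 = SoftplusParams(1, 1, -50, 2.0)  # f == 2
        assert log_likelihood_lnp(p2, d2) == pytest.approx(2 * math.log(2) - 2 - math.log(2))

    def test_matches_scipy_poisson(self):
        p = SoftplusParams(1.2, 1.5, 0.3, 0.2)
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        rates = np.asarray(softplus_eval(p, x))
        r = rng.poisson(rates)
        d = BinnedDataset(x, r)
        ref = float(poisson.logpmf(r, rates).sum())
        assert log_likelihood_lnp(p, d) == pytest.approx(ref, rel=1e-12)

    def test_constant_rate_mle_is_mean(self):
        rng = np.random.default_rng(4)
        r = rng.poisson(3.0, 500)
        d = BinnedDataset(np.zeros(500), r)
        rbar = r.mean()
        ll_at = lambda c: log_likelihood_lnp(SoftplusParams(1, 1, -50, c), d)
        assert ll_at(rbar) > ll_at(rbar * 1.05)
        assert ll_at(rbar) > ll_at(rbar * 0.95)
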