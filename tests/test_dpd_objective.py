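"""Power integrals, the empirical objective W_{n,alpha}, and the DPD."""

import numpy as np
import pytest
from scipy import integrate

from cldic import (BlockSpec, CompositeModel, dpd_distance, power_integral,
                   wn, wn_alpha, wn_zero)
from cldic.divergence import IntegrationError


def bvn_logpdf(mu, rho):
    s = 1 - rho ** 2

    def f(Y):
        z1 = Y[:, 0] - mu[0]
        z2 = Y[:, 1] - mu[1]
        Q = z1 ** 2 - 2 * rho * z1 * z2 + z2 ** 2
        return -np.log(2 * np.pi) - 0.5 * np.log(s) - Q / (2 * s)

    return f


class TestPowerIntegral:
    def test_proper_density_normalizes(self, bvn_model, bvt_model, plan):
        for model in (bvn_model, bvt_model):
            assert power_integral(model, [0.2], 1.0, plan) == pytest.approx(1.0)

    def test_squared_standard_normal(self, bvn_model, plan):
        assert power_integral(bvn_model, [0.0], 2.0, plan) == pytest.approx(
            1.0 / (4 * np.pi), rel=1e-12)

    def test_t_power_against_quadrature(self, bvt_model, plan):
        # Gamma-identity closed form vs an adaptive 2-D quadrature oracle
        rho, c = -0.15, 1.3
        closed = power_integral(bvt_model, [rho], c, plan)
        num = integrate.dblquad(
            lambda y2, y1: np.exp(c * bvt_model.logcl([rho], [[y1, y2]])[0]),
            -60, 60, -60, 60, epsabs=1e-11, epsrel=1e-11)[0]
        assert closed == pytest.approx(num, rel=1e-7)

    def test_decreasing_in_exponent(self, bvn_model, bvt_model, plan):
        # densities bounded by 1: CL^e shrinks pointwise as e grows
        es = np.linspace(1.0, 2.5, 7)
        for model in (bvn_model, bvt_model):
            vals = [power_integral(model, [0.1], float(e), plan) for e in es]
            assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_divergent_t_exponent_raises(self, bvt_model, plan):
        # a = c (nu+2)/2 <= 1 diverges: nu=5 -> c <= 2/7
        with pytest.raises(IntegrationError):
            power_integral(bvt_model, [0.0], 0.2, plan)

    def test_invalid_exponent(self, bvn_model, plan):
        with pytest.raises(ValueError):
            power_integral(bvn_model, [0.0], 0.0, plan)


class TestWnAlpha:
    def test_single_point_hand_value(self, bvn_model, plan):
        # n=1 at the mode, alpha=1: int f^2 - 2 f(mu) = 1/(4 pi) - 1/pi
        val = wn_alpha(bvn_model, [0.0], np.zeros((1, 2)), 1.0, plan)
        assert val == pytest.approx(1.0 / (4 * np.pi) - 1.0 / np.pi, rel=1e-12)

    def test_row_permutation_invariance(self, bvn_model, plan):
        rng = np.random.default_rng(21)
        Y = rng.normal(size=(40, 2))
        a = wn_alpha(bvn_model, [0.3], Y, 0.5, plan)
        b = wn_alpha(bvn_model, [0.3], Y[rng.permutation(40)], 0.5, plan)
        assert a == pytest.approx(b, rel=1e-14)

    def test_alpha_to_zero_limit(self, bvn_model, plan):
        # wn_alpha + 1/alpha -> wn_zero as alpha -> 0
        Y = np.random.default_rng(22).normal(size=(50, 2))
        a = 1e-4
        lim = wn_alpha(bvn_model, [0.2], Y, a, plan) + 1.0 / a
        assert abs(lim - wn_zero(bvn_model, [0.2], Y)) < 1e-3

    def test_alpha_zero_directed_to_wn_zero(self, bvn_model, plan):
        with pytest.raises(ValueError, match="wn_zero"):
            wn_alpha(bvn_model, [0.0], np.zeros((2, 2)), 0.0, plan)
        # the dispatcher handles it
        assert wn(bvn_model, [0.0], np.zeros((2, 2)), 0.0, plan) == \
            pytest.approx(np.log(2 * np.pi))


class TestWnZero:
    def test_mode_value(self, bvn_model):
        val = wn_zero(bvn_model, [0.0], np.zeros((2, 2)))
        assert val == pytest.approx(np.log(2 * np.pi), rel=1e-12)

    def test_duplicating_data_is_invariant(self, bvn_model):
        Y = np.random.default_rng(23).normal(size=(30, 2))
        a = wn_zero(bvn_model, [0.1], Y)
        b = wn_zero(bvn_model, [0.1], np.vstack([Y, Y]))
        assert a == pytest.approx(b, rel=1e-14)


class TestDpdDistance:
    def test_identity_of_indiscernibles(self, plan):
        f = bvn_logpdf((0.0, 0.0), 0.2)
        for alpha in (0.0, 0.3, 1.0):
            assert dpd_distance(f, f, alpha, plan) == pytest.approx(0.0, abs=1e-10)

    def test_non_negative(self, plan):
        g = bvn_logpdf((0.0, 0.0), 0.0)
        f = bvn_logpdf((0.5, -0.3), 0.4)
        for alpha in (0.0, 0.2, 0.5, 1.0):
            assert dpd_distance(g, f, alpha, plan) >= 0.0

    def test_alpha_one_is_l2_distance(self, plan):
        # cross-checked by direct quadrature of the squared difference
        g = bvn_logpdf((0.0, 0.0), 0.0)
        f = bvn_logpdf((0.0, 0.0), 0.2)
        d1 = dpd_distance(g, f, 1.0, plan)
        l2 = integrate.dblquad(
            lambda y2, y1: (np.exp(f(np.array([[y1, y2]]))[0])
                            - np.exp(g(np.array([[y1, y2]]))[0])) ** 2,
            -12, 12, -12, 12, epsabs=1e-12, epsrel=1e-12)[0]
        assert d1 == pytest.approx(l2, rel=1e-8)

    def test_alpha_to_zero_matches_gaussian_kl(self, plan):
        # KL between two bivariate normals in closed form
        rho_g, rho_f = 0.0, 0.2
        g = bvn_logpdf((0.0, 0.0), rho_g)
        f = bvn_logpdf((0.0, 0.0), rho_f)
        Sg = np.array([[1, rho_g], [rho_g, 1.0]])
        Sf = np.array([[1, rho_f], [rho_f, 1.0]])
        kl = 0.5 * (np.trace(np.linalg.solve(Sf, Sg)) - 2
                    + np.log(np.linalg.det(Sf) / np.linalg.det(Sg)))
        assert dpd_distance(g, f, 1e-4, plan) == pytest.approx(kl, abs=1e-3)
        assert dpd_distance(g, f, 0.0, plan) == pytest.approx(kl, rel=1e-8)
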