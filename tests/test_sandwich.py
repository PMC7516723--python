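"""Sensitivity/variability matrices and the trace penalty."""

import numpy as np
import pytest

from cldic import (empirical_godambe, penalty_trace, sample,
                   sandwich_matrices)
from cldic.sandwich import SandwichMatrices, SingularSensitivityError
from cldic.scenarios import scenario_models

RHO0 = -0.15


def fisher_rho(rho):
    """Fisher information for the correlation of a unit-variance bivariate
    normal: (1 + rho^2) / (1 - rho^2)^2."""
    return (1 + rho ** 2) / (1 - rho ** 2) ** 2


class TestHMatrix:
    def test_scalar_h_is_nonnegative(self, bvn_model, bvt_model, plan):
        for model in (bvn_model, bvt_model):
            for alpha in (0.0, 0.3, 0.7):
                for rho in (-0.5, 0.0, 0.4):
                    sw = sandwich_matrices(model, [rho], alpha, plan)
                    assert sw.H[0, 0] >= 0.0

    def test_alpha0_equals_fisher_information(self, bvn_model, plan):
        for rho in (-0.3, 0.0, 0.5):
            sw = sandwich_matrices(bvn_model, [rho], 0.0, plan)
            assert sw.H[0, 0] == pytest.approx(fisher_rho(rho), rel=1e-9)

    def test_alpha0_matches_monte_carlo_second_moment(self, bvn_model,
                                                      bvn_dgp, plan):
        data = sample(bvn_dgp, 100_000, seed=51)
        u = bvn_model.score([RHO0], data.values)[:, 0]
        mc, se = (u ** 2).mean(), (u ** 2).std() / np.sqrt(len(u))
        sw = sandwich_matrices(bvn_model, [RHO0], 0.0, plan)
        assert abs(sw.H[0, 0] - mc) < 3 * se


class TestJMatrix:
    def test_psd_over_grid(self, plan):
        cand = scenario_models("1a", nu=5)
        for model in cand.values():
            for alpha in (0.0, 0.3, 0.7):
                for rho in (-0.19, 0.0, 0.2, 0.33):
                    sw = sandwich_matrices(model, [rho], alpha, plan)
                    assert np.linalg.eigvalsh(sw.J).min() >= -1e-10
                    np.testing.assert_allclose(sw.J, sw.J.T, atol=1e-10)

    def test_information_identity_at_alpha0(self, bvn_model, plan):
        # proper composite density: centering vanishes and J = H exactly
        sw = sandwich_matrices(bvn_model, [0.3], 0.0, plan)
        np.testing.assert_allclose(sw.J, sw.H, rtol=1e-12)


class TestFactorizedVsBruteForce:
    def test_two_block_model_agrees_with_direct_4d_quadrature(self, plan):
        """The cross-block factorization against a direct 4-D tensor rule
        built only from model.logcl / model.score."""
        from cldic.quadrature import tan_map_2d
        cand = scenario_models("1a", nu=5)
        W, wt = tan_map_2d(36, 2.0)
        for name, model in cand.items():
            mu = np.array([b.mean for b in model.blocks]).ravel()
            Y = np.column_stack([
                np.repeat(W[:, 0], len(W)), np.repeat(W[:, 1], len(W)),
                np.tile(W[:, 0], len(W)), np.tile(W[:, 1], len(W))]) + mu
            wts = np.repeat(wt, len(wt)) * np.tile(wt, len(wt))
            for rho, alpha in ((-0.1, 0.3), (0.2, 0.5)):
                logcl = model.logcl([rho], Y)
                u = model.score([rho], Y)[:, 0]
                sw = sandwich_matrices(model, [rho], alpha, plan)
                H_bf = float(wts @ (np.exp((1 + alpha) * logcl) * u * u))
                xi_bf = float(wts @ (np.exp((1 + alpha) * logcl) * u))
                J_bf = float(wts @ (np.exp((2 * alpha + 1) * logcl) * u * u)) \
                    - xi_bf ** 2
                assert abs(sw.H[0, 0] / H_bf - 1) < 1e-5
                assert abs(sw.J[0, 0] / J_bf - 1) < 1e-5

    def test_qmc_route_agrees_loosely(self, bvn_model, plan):
        from dataclasses import replace
        from cldic import build_qmc_nodes
        big = replace(plan, qmc_nodes=2 ** 16)
        nodes = build_qmc_nodes(bvn_model, big, theta_ref=[RHO0])
        sw_f = sandwich_matrices(bvn_model, [RHO0], 0.3, plan)
        sw_q = sandwich_matrices(bvn_model, [RHO0], 0.3,
                                 replace(big, method="qmc"), nodes=nodes)
        assert sw_q.H[0, 0] == pytest.approx(sw_f.H[0, 0], rel=5e-3)
        assert sw_q.J[0, 0] == pytest.approx(sw_f.J[0, 0], rel=5e-3)


class TestPenaltyTrace:
    def test_aic_type_penalty_for_full_likelihood(self, bvn_model, plan):
        # correctly specified full likelihood at alpha=0: n * penalty = p
        sw = sandwich_matrices(bvn_model, [0.2], 0.0, plan)
        assert 100 * penalty_trace(sw, 100) == pytest.approx(1.0, rel=1e-10)

    def test_doubling_n_halves_penalty(self, bvt_model, plan):
        sw = sandwich_matrices(bvt_model, [0.1], 0.3, plan)
        assert penalty_trace(sw, 50) == pytest.approx(2 * penalty_trace(sw, 100))

    def test_scalar_arithmetic(self, plan):
        sw = SandwichMatrices(H=np.array([[2.0]]), J=np.array([[0.5]]),
                              alpha=0.3, theta=np.array([0.0]))
        assert penalty_trace(sw, 10) == pytest.approx(1.3 * 0.5 / (10 * 2.0))

    def test_singular_sensitivity_raises(self):
        sw = SandwichMatrices(H=np.array([[0.0]]), J=np.array([[1.0]]),
                              alpha=0.0, theta=np.array([0.0]))
        with pytest.raises(SingularSensitivityError):
            sw.trace_ratio()


def test_empirical_godambe_matches_fisher(bvn_model, bvn_dgp, plan):
    """Correct specification: H = J = G* = Fisher, all within MC error."""
    data = sample(bvn_dgp, 50_000, seed=61)
    H, J, G = empirical_godambe(bvn_model, [RHO0], data)
    fisher = fisher_rho(RHO0)
    for M in (H, J, G):
        assert M[0, 0] == pytest.approx(fisher, rel=0.05)
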