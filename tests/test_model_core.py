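"""Composite log-densities, scores and the mixture sampler."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gamma

from cldic import (BlockSpec, CompositeModel, DataSample, DGPComponent,
                   MixtureDGP, sample)
from cldic.blocks import DegenerateCovarianceError
from cldic.models import ParameterBoundsError
from cldic.scenarios import scenario_dgp, sigma_matrix

LOG2PI = np.log(2 * np.pi)


def two_block_normal(rho_name="rho"):
    blocks = tuple(
        BlockSpec(variables=v, family="bivariate-normal", mean=(0.0, 0.0),
                  sigmas=(1.0, 1.0), rho=rho_name)
        for v in ((1, 2), (3, 4)))
    return CompositeModel(m=4, blocks=blocks, theta_names=(rho_name,),
                          bounds=((-0.95, 0.95),))


class TestCompositeLogDensity:
    def test_standard_normal_mode(self, bvn_model):
        assert np.isclose(bvn_model.logcl([0.0], [[0.0, 0.0]])[0], -LOG2PI)

    def test_additivity_over_blocks(self):
        model = two_block_normal()
        val = model.logcl([0.0], [np.zeros(4)])[0]
        assert np.isclose(val, -2 * LOG2PI)

    def test_t_block_matches_direct_formula(self):
        # independent evaluation: C_2 |S|^{-1/2} at the mode, with
        # C_2 = (pi nu)^{-1} Gamma((nu+2)/2)/Gamma(nu/2) and S = ((nu-2)/nu) Sigma0
        nu, rho = 5.0, -0.15
        b = BlockSpec(variables=(1, 2), family="bivariate-t", mean=(1.0, -2.0),
                      sigmas=(1.0, 1.0), rho="rho", df=nu)
        model = CompositeModel(m=2, blocks=(b,), theta_names=("rho",),
                               bounds=((-0.95, 0.95),))
        C2 = gamma((nu + 2) / 2) / (gamma(nu / 2) * np.pi * nu)
        detS = ((nu - 2) / nu) ** 2 * (1 - rho ** 2)
        expect = np.log(C2 / np.sqrt(detS))
        assert np.isclose(model.logcl([rho], [[1.0, -2.0]])[0], expect, rtol=1e-12)

    def test_block_order_invariance(self):
        b12 = BlockSpec(variables=(1, 2), family="bivariate-normal",
                        mean=(0.0, 1.0), sigmas=(1.0, 2.0), rho="rho")
        b34 = BlockSpec(variables=(3, 4), family="bivariate-t", df=6.0,
                        mean=(0.5, 0.0), sigmas=(1.0, 1.0), rho="rho")
        m1 = CompositeModel(m=4, blocks=(b12, b34), theta_names=("rho",),
                            bounds=((-0.9, 0.9),))
        m2 = CompositeModel(m=4, blocks=(b34, b12), theta_names=("rho",),
                            bounds=((-0.9, 0.9),))
        Y = np.random.default_rng(3).normal(size=(20, 4))
        np.testing.assert_allclose(m1.logcl([0.2], Y), m2.logcl([0.2], Y))

    def test_out_of_bounds_theta_rejected(self, bvn_model):
        with pytest.raises(ParameterBoundsError):
            bvn_model.logcl([0.99], [[0.0, 0.0]])

    def test_degenerate_correlation_rejected(self):
        b = BlockSpec(variables=(1, 2), family="bivariate-normal",
                      mean=(0.0, 0.0), sigmas=(1.0, 1.0), rho="rho")
        m = CompositeModel(m=2, blocks=(b,), theta_names=("rho",),
                           bounds=((-2.0, 2.0),))
        with pytest.raises(DegenerateCovarianceError):
            m.logcl([1.5], [[0.0, 0.0]])

    def test_proper_density_integrates_to_one(self, plan):
        # brute-force 4-D tensor quadrature of exp(log CL) for a
        # two-block partition model (normal and t blocks)
        from cldic.quadrature import tan_map_2d
        for fam, kw in (("bivariate-normal", {}), ("bivariate-t", {"df": 5.0})):
            blocks = tuple(
                BlockSpec(variables=v, family=fam, mean=(0.3, -0.2),
                          sigmas=(1.0, 1.0), rho="rho", **kw)
                for v in ((1, 2), (3, 4)))
            model = CompositeModel(m=4, blocks=blocks, theta_names=("rho",),
                                   bounds=((-0.9, 0.9),))
            W, wt = tan_map_2d(40, 2.0)
            # tensor the 2-D rule with itself; integrand factors over blocks
            # only through the model call, not in this oracle's construction
            Y = np.column_stack([
                np.repeat(W[:, 0], len(W)), np.repeat(W[:, 1], len(W)),
                np.tile(W[:, 0], len(W)), np.tile(W[:, 1], len(W))])
            Y[:, :2] += 0.3, -0.2
            Y[:, 2:] += 0.3, -0.2
            vals = np.exp(model.logcl([-0.15], Y))
            total = float(np.repeat(wt, len(wt)) @ (vals * np.tile(wt, len(wt))))
            assert abs(total - 1.0) < 1e-6


class TestCompositeScore:
    @pytest.mark.parametrize("model_name", ["bvn_model", "bvt_model"])
    def test_matches_finite_differences(self, model_name, request):
        model = request.getfixturevalue(model_name)
        rng = np.random.default_rng(42)
        for _ in range(20):
            rho = rng.uniform(-0.7, 0.7)
            y = rng.normal(size=(1, 2)) * 2.0
            h = 1e-6
            fd = (model.logcl([rho + h], y) - model.logcl([rho - h], y)) / (2 * h)
            an = model.score([rho], y)[0, 0]
            assert abs(an - fd[0]) <= 1e-5 * max(1.0, abs(fd[0]))

    def test_zero_at_mode_with_zero_correlation(self, bvn_model):
        assert bvn_model.score([0.0], [[0.0, 0.0]])[0, 0] == pytest.approx(0.0)

    def test_zero_mean_under_the_model(self, bvn_model, bvn_dgp):
        data = sample(bvn_dgp, 100_000, seed=7)
        u = bvn_model.score([-0.15], data.values)[:, 0]
        assert abs(u.mean()) < 3 * u.std() / np.sqrt(len(u))

    def test_generic_block_finite_difference_fallback(self):
        def logpdf(theta, Y):
            r = theta["rho"]
            s = 1 - r * r
            Q = Y[:, 0] ** 2 - 2 * r * Y[:, 0] * Y[:, 1] + Y[:, 1] ** 2
            return -LOG2PI - 0.5 * np.log(s) - Q / (2 * s)

        g = BlockSpec(variables=(1, 2), family="generic", logpdf=logpdf,
                      free=("rho",))
        gm = CompositeModel(m=2, blocks=(g,), theta_names=("rho",),
                            bounds=((-0.9, 0.9),))
        b = BlockSpec(variables=(1, 2), family="bivariate-normal",
                      mean=(0.0, 0.0), sigmas=(1.0, 1.0), rho="rho")
        bm = CompositeModel(m=2, blocks=(b,), theta_names=("rho",),
                            bounds=((-0.9, 0.9),))
        Y = np.random.default_rng(5).normal(size=(10, 2))
        np.testing.assert_allclose(gm.score([0.3], Y), bm.score([0.3], Y),
                                   atol=1e-6)


class TestMixtureSampling:
    def test_pure_normal_covariance(self):
        dgp = scenario_dgp("1a", -0.15, omega=1.0, nu=5)
        d = sample(dgp, 100_000, seed=11)
        S = sigma_matrix(-0.15)
        err = np.abs(np.cov(d.values.T) - S)
        assert err.max() < 3 * 6.0 / np.sqrt(d.n)  # 3 sigma, generous moment bound

    def test_t_component_covariance_equals_sigma(self):
        # Sigma* = ((nu-2)/nu) Sigma as sampling shape gives covariance Sigma
        dgp = scenario_dgp("1a", -0.15, omega=0.0, nu=10)
        d = sample(dgp, 150_000, seed=12)
        S = sigma_matrix(-0.15)
        assert np.abs(np.cov(d.values.T) - S).max() < 0.03

    def test_mixture_mean(self):
        dgp = scenario_dgp("1a", -0.15, omega=0.25, nu=5)
        d = sample(dgp, 100_000, seed=13)
        mu = 0.25 * np.array([0, 0, 0.5, 0]) + 0.75 * np.array([3.2, 1.5, 0.5, 2])
        assert np.abs(d.values.mean(axis=0) - mu).max() < 0.05

    def test_same_seed_is_deterministic(self, normal_dgp_full):
        a = sample(normal_dgp_full, 50, seed=99)
        b = sample(normal_dgp_full, 50, seed=99)
        np.testing.assert_array_equal(a.values, b.values)

    def test_stratified_assignment_counts(self):
        dgp = scenario_dgp("1a", -0.15, omega=0.5, nu=5)
        d = sample(dgp, 101, seed=1, assignment="stratified")
        assert d.n == 101

    def test_non_pd_covariance_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            DGPComponent("normal", 1.0, (0.0, 0.0), bad)


class TestDataSample:
    def test_rejects_missing_values(self):
        with pytest.raises(ValueError):
            DataSample(np.array([[1.0, np.nan], [0.0, 1.0]]))

    def test_csv_round_trip(self, tmp_path):
        d = DataSample(np.random.default_rng(0).normal(size=(5, 4)))
        p = tmp_path / "d.csv"
        d.to_csv(p)
        back = DataSample.from_csv(p)
        np.testing.assert_allclose(back.values, d.values)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(rho=st.floats(-0.8, 0.8), y1=st.floats(-3, 3), y2=st.floats(-3, 3))
def test_weight_scales_logdensity_linearly(rho, y1, y2):
    """Doubling a block weight doubles its log-density contribution."""
    def model(w):
        b = BlockSpec(variables=(1, 2), family="bivariate-normal",
                      mean=(0.0, 0.0), sigmas=(1.0, 1.0), rho="rho", weight=w)
        return CompositeModel(m=2, blocks=(b,), theta_names=("rho",),
                              bounds=((-0.95, 0.95),))
    v1 = model(1.0).logcl([rho], [[y1, y2]])[0]
    v2 = model(2.0).logcl([rho], [[y1, y2]])[0]
    assert np.isclose(v2, 2 * v1, rtol=1e-12, atol=1e-12)
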