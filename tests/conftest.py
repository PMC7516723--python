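"""Shared fixtures: small reference models and datasets."""

import numpy as np
import pytest

from cldic import (BlockSpec, CompositeModel, DGPComponent, IntegralPlan,
                   MixtureComposite, MixtureDGP, sample)
from cldic.scenarios import scenario_dgp, scenario_models

RHO0 = -0.15


@pytest.fixture(scope="session")
def plan():
    return IntegralPlan()


@pytest.fixture(scope="session")
def bvn_block():
    """Standard bivariate-normal block with free correlation."""
    return BlockSpec(variables=(1, 2), family="bivariate-normal",
                     mean=(0.0, 0.0), sigmas=(1.0, 1.0), rho="rho")


@pytest.fixture(scope="session")
def bvn_model(bvn_block):
    """Single-block full likelihood: a proper bivariate normal on R^2."""
    return CompositeModel(m=2, blocks=(bvn_block,), theta_names=("rho",),
                          bounds=((-0.95, 0.95),), name="bvn")


@pytest.fixture(scope="session")
def bvt_model():
    """Single-block bivariate t (nu=5) with free correlation."""
    b = BlockSpec(variables=(1, 2), family="bivariate-t", mean=(0.0, 0.0),
                  sigmas=(1.0, 1.0), rho="rho", df=5.0)
    return CompositeModel(m=2, blocks=(b,), theta_names=("rho",),
                          bounds=((-0.95, 0.95),), name="bvt")


@pytest.fixture(scope="session")
def scenario_candidates():
    """The paired-marginal normal and t (nu=5) candidates of the first study."""
    return scenario_models("1a", nu=5)


@pytest.fixture(scope="session")
def normal_dgp_full():
    """4-variate normal truth with the full cross-correlated covariance."""
    return scenario_dgp("1a", RHO0, omega=1.0, nu=5)


@pytest.fixture(scope="session")
def bvn_dgp():
    cov = np.array([[1.0, RHO0], [RHO0, 1.0]])
    return MixtureDGP(components=(DGPComponent("normal", 1.0, (0.0, 0.0), cov),))


@pytest.fixture(scope="session")
def bvn_data(bvn_dgp):
    return sample(bvn_dgp, 500, seed=101)
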