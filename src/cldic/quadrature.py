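"""Numerical integration backends.

Three routes are used throughout the package:

* closed forms, whenever a power of a bivariate normal or bivariate t
  density is integrated over the plane;
* tensor-product quadrature on a whitened scale for the 2-D score-moment
  integrals of single blocks (Gauss-Hermite for Gaussian weights, a
  tangent-mapped Gauss-Legendre rule for algebraically decaying t tails);
* frozen-node quasi-Monte-Carlo importance sampling for composite densities
  that do not factorize over blocks (mixtures of composite likelihoods).

The QMC node set is generated once per :class:`IntegralPlan` and reused for
every objective evaluation inside an optimization run, so that the empirical
divergence is a smooth function of the parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.stats import qmc


@dataclass(frozen=True)
class IntegralPlan:
    """Settings for the numerical realization of integrals over R^m.

    Parameters
    ----------
    method:
        ``"auto"`` picks closed forms when available, then tensor
        quadrature, then QMC.  ``"closed-form"``, ``"quadrature"`` and
        ``"qmc"`` force a route (an error is raised when the forced route
        does not apply).
    quad_nodes:
        Per-axis Gauss-Legendre node count of the tangent-mapped rule.
    tan_scale:
        Scale of the tangent map, in whitened (unit-variance) coordinate
        units.
    qmc_nodes:
        Number of quasi-Monte-Carlo nodes (rounded up to a power of two).
    qmc_seed:
        Scrambling seed of the Sobol sequence; fixing it freezes the node
        set and makes all QMC-backed quantities deterministic.
    tolerance:
        Target relative accuracy of quadrature integrals; used for
        self-checks against closed forms.
    """

    method: str = "auto"
    quad_nodes: int = 120
    tan_scale: float = 2.0
    qmc_nodes: int = 8192
    qmc_seed: int = 0
    tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.method not in ("auto", "closed-form", "quadrature", "qmc"):
            raise ValueError(f"unknown integration method {self.method!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.qmc_nodes < 256:
            raise ValueError("qmc_nodes must be at least 256")

    def with_seed(self, seed: int) -> "IntegralPlan":
        return replace(self, qmc_seed=int(seed))


DEFAULT_PLAN = IntegralPlan()


@lru_cache(maxsize=32)
def gauss_hermite_2d(nodes: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Tensor probabilists' Gauss-Hermite rule on R^2.

    Returns points ``W`` of shape (nodes**2, 2) and weights ``wt`` such that
    ``sum(wt * g(W))`` approximates ``int exp(-|w|^2/2) g(w) dw`` (exactly,
    for polynomial ``g`` of per-axis degree < 2*nodes).
    """
    x, w = np.polynomial.hermite_e.hermegauss(nodes)
    W1, W2 = np.meshgrid(x, x, indexing="ij")
    WT1, WT2 = np.meshgrid(w, w, indexing="ij")
    W = np.column_stack([W1.ravel(), W2.ravel()])
    return W, (WT1 * WT2).ravel()


@lru_cache(maxsize=32)
def tan_map_2d(nodes: int = 120, scale: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Tangent-mapped tensor Gauss-Legendre rule on R^2.

    Substituting ``w_i = scale * tan(t_i)`` maps the plane onto the open
    square (-pi/2, pi/2)^2; algebraic tail decay of the integrand becomes a
    high-order zero at the boundary, which Gauss-Legendre resolves to near
    machine precision.  Returns points (nodes**2, 2) and weights including
    the Jacobian, so ``sum(wt * g(W)) ~ int_{R^2} g(w) dw``.
    """
    x, w = np.polynomial.legendre.leggauss(nodes)
    t = x * (np.pi / 2)
    wt = w * (np.pi / 2)
    pts = scale * np.tan(t)
    jac = scale / np.cos(t) ** 2
    W1, W2 = np.meshgrid(pts, pts, indexing="ij")
    J1, J2 = np.meshgrid(wt * jac, wt * jac, indexing="ij")
    W = np.column_stack([W1.ravel(), W2.ravel()])
    return W, (J1 * J2).ravel()


def sobol_uniforms(n_points: int, dim: int, seed: int) -> np.ndarray:
    """Scrambled Sobol points in (0,1)^dim, n rounded up to a power of two."""
    m = max(8, int(np.ceil(np.log2(n_points))))
    eng = qmc.Sobol(d=dim, scramble=True, seed=int(seed))
    u = eng.random_base2(m)
    # guard against exact 0/1 which break inverse-CDF maps
    return np.clip(u, 1e-12, 1 - 1e-12)
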