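"""Sensitivity and variability matrices of the tilted composite score.

With u(theta, y) the composite score, the criterion uses

    H_a(theta) = int CL^(1+a) u u^T dy
    J_a(theta) = int CL^(2a+1) u u^T dy - xi xi^T,
    xi         = int CL^(1+a) u dy,

and the model-complexity penalty (a+1)/n * trace(J_a H_a^{-1}).  At a = 0
for a proper composite density, xi = 0 (it is the gradient of a constant
normalization) and H_0 = J_0, so the penalty reduces to p/n, the
Akaike-type count of free parameters.

For a product composite likelihood every integral splits over (block,
block) pairs into products of 2-D score-moment integrals; mixtures of
composite densities fall back to frozen-node QMC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .blocks import block_moments
from .models import (CompositeModel, MixtureComposite, ModelLike, QMCNodes,
                     as_matrix, build_qmc_nodes)
from .quadrature import DEFAULT_PLAN, IntegralPlan


class SingularSensitivityError(np.linalg.LinAlgError):
    pass


@dataclass(frozen=True)
class SandwichMatrices:
    H: np.ndarray
    J: np.ndarray
    alpha: float
    theta: np.ndarray

    def __post_init__(self) -> None:
        H = 0.5 * (np.asarray(self.H) + np.asarray(self.H).T)
        J = 0.5 * (np.asarray(self.J) + np.asarray(self.J).T)
        object.__setattr__(self, "H", H)
        object.__setattr__(self, "J", J)

    @property
    def p(self) -> int:
        return self.H.shape[0]

    def trace_ratio(self) -> float:
        """trace(J H^{-1}) via a linear solve (no explicit inverse)."""
        cond = np.linalg.cond(self.H)
        if not np.isfinite(cond) or cond > 1e12:
            raise SingularSensitivityError(
                f"sensitivity matrix ill-conditioned (cond={cond:.3e})")
        return float(np.trace(np.linalg.solve(self.H, self.J)))

    def asymptotic_covariance(self) -> np.ndarray:
        """H^{-1} J H^{-1}, the limiting covariance of sqrt(n)(theta_hat - theta)."""
        Hinv_J = np.linalg.solve(self.H, self.J)
        return np.linalg.solve(self.H, Hinv_J.T).T


def _product_integrals(model: CompositeModel, theta, c: float,
                       plan: IntegralPlan) -> tuple[float, np.ndarray, np.ndarray]:
    """(P, xi, K) = (int CL^c, int CL^c u, int CL^c u u^T) for product models.

    Block k enters CL^c at exponent c * w_k and its score scaled by w_k.
    Cross-block terms are products of first moments; same-block terms use
    the block's second-moment integral.
    """
    td = model.theta_dict(theta)
    p = model.p
    M0s, M1s, M2s = [], [], []
    for b in model.blocks:
        m0, m1, m2 = block_moments(b, td, c * b.weight, plan)
        g1 = np.zeros(p)
        g2 = np.zeros((p, p))
        idx = [model.free_index(nm) for nm in b.free_names]
        for a_loc, a_glob in enumerate(idx):
            g1[a_glob] += b.weight * m1[a_loc]
            for b_loc, b_glob in enumerate(idx):
                g2[a_glob, b_glob] += b.weight ** 2 * m2[a_loc, b_loc]
        M0s.append(m0); M1s.append(g1); M2s.append(g2)
    P = float(np.prod(M0s))
    xi = np.zeros(p)
    K = np.zeros((p, p))
    for k in range(len(model.blocks)):
        xi += M1s[k] / M0s[k]
        K += M2s[k] / M0s[k]
        for l in range(len(model.blocks)):
            if l != k:
                K += np.outer(M1s[k] / M0s[k], M1s[l] / M0s[l])
    return P, P * xi, P * K


def _qmc_integrals(model: ModelLike, theta, c: float, plan: IntegralPlan,
                   nodes: QMCNodes) -> tuple[float, np.ndarray, np.ndarray]:
    w = np.exp(c * model.logcl(theta, nodes.Y) - nodes.logq)
    U = model.score(theta, nodes.Y)
    n = w.shape[0]
    P = float(w.mean())
    xi = (w @ U) / n
    K = (U.T * w) @ U / n
    return P, xi, K


def _integrals(model, theta, c, plan, nodes):
    closed_ok = (isinstance(model, CompositeModel) and model.all_builtin
                 and model.is_disjoint and model.covers_all)
    if plan.method != "qmc" and closed_ok:
        return _product_integrals(model, theta, c, plan)
    if nodes is None:
        nodes = build_qmc_nodes(
            model, plan,
            theta_ref=theta if isinstance(model, CompositeModel) else None)
    return _qmc_integrals(model, theta, c, plan, nodes)


def sandwich_matrices(model: ModelLike, theta: Sequence[float], alpha: float,
                      plan: IntegralPlan = DEFAULT_PLAN,
                      nodes: Optional[QMCNodes] = None) -> SandwichMatrices:
    """Compute H_alpha and J_alpha together (sharing the moment table)."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    theta = model.check_theta(theta)
    _, xi, H = _integrals(model, theta, 1.0 + alpha, plan, nodes)
    if alpha == 0:
        # xi = grad of the (unit) normalization: exactly zero for proper CL
        if getattr(model, "is_partition", False):
            xi = np.zeros_like(xi)
        J = H - np.outer(xi, xi)
    else:
        _, _, K2 = _integrals(model, theta, 2.0 * alpha + 1.0, plan, nodes)
        J = K2 - np.outer(xi, xi)
    return SandwichMatrices(H=H, J=J, alpha=float(alpha), theta=np.asarray(theta))


def h_matrix(model, theta, alpha, plan: IntegralPlan = DEFAULT_PLAN,
             nodes=None) -> np.ndarray:
    return sandwich_matrices(model, theta, alpha, plan, nodes).H


def j_matrix(model, theta, alpha, plan: IntegralPlan = DEFAULT_PLAN,
             nodes=None) -> np.ndarray:
    return sandwich_matrices(model, theta, alpha, plan, nodes).J


def penalty_trace(sw: SandwichMatrices, n: int) -> float:
    """(alpha + 1)/n * trace(J_alpha H_alpha^{-1})."""
    if n < 1:
        raise ValueError("n must be positive")
    return (sw.alpha + 1.0) / n * sw.trace_ratio()


def empirical_sandwich_matrices(model: ModelLike, theta: Sequence[float],
                                alpha: float, data,
                                plan: IntegralPlan = DEFAULT_PLAN,
                                nodes: Optional[QMCNodes] = None,
                                fd_step: float = 1e-4) -> SandwichMatrices:
    """Sample-based estimates of H_alpha and J_alpha.

    J is the centered empirical covariance of the tilted score CL^alpha u;
    H is the observed Hessian of the empirical objective W_{n,alpha} at
    ``theta``, divided by (1 + alpha).  Both converge to the model-integral
    matrices when the data follow the composite density; under
    misspecification they carry the data's own variability, which is what
    a finite-sample mean-squared-error estimate wants to see.
    """
    from .divergence import wn  # local import: avoids a module cycle

    theta = np.asarray(model.check_theta(theta), dtype=float)
    Y = as_matrix(data)
    n = Y.shape[0]
    u = model.score(theta, Y)
    w = np.exp(alpha * model.logcl(theta, Y))
    psibar = (w[:, None] * u).mean(axis=0)
    J = (u.T * (w * w)) @ u / n - np.outer(psibar, psibar)
    p = theta.shape[0]
    f = lambda t: wn(model, t, Y, alpha, plan, nodes=nodes)
    f0 = f(theta)
    H = np.zeros((p, p))
    for i in range(p):
        ei = np.zeros(p); ei[i] = fd_step
        H[i, i] = (f(theta + ei) - 2.0 * f0 + f(theta - ei)) / fd_step ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p); ej[j] = fd_step
            H[i, j] = H[j, i] = (f(theta + ei + ej) - f(theta + ei - ej)
                                 - f(theta - ei + ej) + f(theta - ei - ej)) \
                / (4.0 * fd_step ** 2)
    H /= (1.0 + alpha)
    return SandwichMatrices(H=H, J=J, alpha=float(alpha), theta=theta)


# ---------------------------------------------------------------------------
# Godambe information under an empirical (true-model) measure
# ---------------------------------------------------------------------------

def empirical_godambe(model: ModelLike, theta: Sequence[float], data,
                      fd_step: float = 1e-5) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sensitivity H = E[-du/dtheta], variability J = E[u u^T] and the
    Godambe information G* = H J^{-1} H, with expectations replaced by
    sample means over ``data`` (drawn from the distribution of interest).

    This is the maximum-likelihood-theory sandwich for the composite MLE;
    under a correctly specified full likelihood H = J = Fisher information.
    """
    theta = model.check_theta(theta)
    Y = as_matrix(data)
    U = model.score(theta, Y)
    J = U.T @ U / Y.shape[0]
    p = len(theta)
    H = np.zeros((p, p))
    for j in range(p):
        step = np.zeros(p); step[j] = fd_step
        dU = (model.score(theta + step, Y) - model.score(theta - step, Y)) / (2 * fd_step)
        H[:, j] = -dU.mean(axis=0)
    H = 0.5 * (H + H.T)
    Gstar = H @ np.linalg.solve(J, H)
    return H, J, Gstar
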