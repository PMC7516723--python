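"""Marginal blocks of a composite likelihood.

A composite likelihood is a weighted product of low-dimensional marginal
densities, each acting on a subset ``A_k`` of the coordinates of the
observation vector.  This module implements the two analytic families used
throughout the package -- the bivariate normal and the bivariate Student t
-- plus a hook for user-supplied ("generic") log-densities.

Parameterization of built-in blocks
-----------------------------------
A built-in block stores a fixed location ``mean``, fixed marginal standard
deviations ``sigmas`` and (for t blocks) the degrees of freedom ``df``; its
only estimable quantity is the correlation ``rho``, given either as a fixed
number or as the *name* of an entry of the model parameter vector.  For a t
block we store the *covariance* scale: with correlation matrix ``R(rho)``
and ``D = diag(sigmas)`` the covariance is ``D R D`` and the t shape matrix
is ``S = ((df-2)/df) * D R D``, so normal and t blocks with the same
``sigmas``/``rho`` have identical second moments.  This requires ``df > 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.special import gammaln, ndtri
from scipy.stats import t as student_t

from .quadrature import IntegralPlan, gauss_hermite_2d, tan_map_2d

FAMILIES = ("bivariate-normal", "bivariate-t", "generic")

LOG2PI = np.log(2.0 * np.pi)


class DegenerateCovarianceError(ValueError):
    """Raised when a block correlation leaves the open interval (-1, 1)."""


@dataclass(frozen=True)
class BlockSpec:
    """One marginal component ``f_{A_k}`` of a composite likelihood.

    Parameters
    ----------
    variables:
        1-based coordinate indices (the set ``A_k``); converted to 0-based
        internally (see :meth:`indices0`, the single place the convention
        is applied).
    family:
        ``"bivariate-normal"``, ``"bivariate-t"`` or ``"generic"``.
    mean, sigmas:
        Fixed location and marginal standard deviations (built-ins).
    rho:
        Correlation: a float fixes it, a string names the free parameter.
    df:
        Degrees of freedom, t blocks only; must exceed 2.
    weight:
        Non-negative composite-likelihood weight ``w_k``.
    logpdf:
        Generic blocks: callable ``logpdf(theta: dict, y: (n,d)) -> (n,)``.
    free:
        Generic blocks: names of model parameters the callable reads.
    center:
        Generic blocks: quadrature center for moment integrals.
    """

    variables: tuple[int, ...]
    family: str
    mean: tuple[float, ...] = ()
    sigmas: tuple[float, ...] = ()
    rho: float | str = 0.0
    df: Optional[float] = None
    weight: float = 1.0
    logpdf: Optional[Callable] = None
    free: tuple[str, ...] = ()
    center: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown block family {self.family!r}")
        if not self.variables:
            raise ValueError("block needs at least one variable index")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variable indices in block")
        if min(self.variables) < 1:
            raise ValueError("variable indices are 1-based and must be >= 1")
        if self.weight < 0:
            raise ValueError("block weight must be non-negative")
        if self.family in ("bivariate-normal", "bivariate-t"):
            if len(self.variables) != 2:
                raise ValueError(f"{self.family} blocks act on exactly 2 coordinates")
            if len(self.mean) != 2 or len(self.sigmas) != 2:
                raise ValueError("built-in blocks need 2-vector mean and sigmas")
            if min(self.sigmas) <= 0:
                raise ValueError("sigmas must be positive")
        if self.family == "bivariate-t":
            if self.df is None or self.df <= 2:
                raise ValueError("t blocks need df > 2 so the covariance exists")
        if self.family == "generic" and self.logpdf is None:
            raise ValueError("generic blocks need a logpdf callable")

    @property
    def indices0(self) -> np.ndarray:
        """0-based coordinate indices (internal convention)."""
        return np.asarray(self.variables, dtype=int) - 1

    @property
    def free_names(self) -> tuple[str, ...]:
        if self.family == "generic":
            return self.free
        return (self.rho,) if isinstance(self.rho, str) else ()

    def rho_value(self, theta: dict[str, float]) -> float:
        r = theta[self.rho] if isinstance(self.rho, str) else float(self.rho)
        if not -1.0 < r < 1.0:
            raise DegenerateCovarianceError(f"block correlation {r} outside (-1, 1)")
        return r


# ---------------------------------------------------------------------------
# standardized-coordinate helpers
# ---------------------------------------------------------------------------

def _standardize(block: BlockSpec, Y: np.ndarray) -> np.ndarray:
    mu = np.asarray(block.mean)
    sig = np.asarray(block.sigmas)
    return (Y - mu) / sig


def _bvn_core(Z: np.ndarray, rho: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Return (Q, z1*z2, s) for standardized points Z, with s = 1 - rho^2."""
    s = 1.0 - rho * rho
    z1, z2 = Z[..., 0], Z[..., 1]
    cross = z1 * z2
    Q = z1 * z1 - 2.0 * rho * cross + z2 * z2
    return Q, cross, s


def _chol2(rho: float) -> np.ndarray:
    return np.array([[1.0, 0.0], [rho, np.sqrt(1.0 - rho * rho)]])


# ---------------------------------------------------------------------------
# log-density and score
# ---------------------------------------------------------------------------

def block_loglik(block: BlockSpec, theta: dict[str, float], Y: np.ndarray) -> np.ndarray:
    """Unweighted block log-density at the rows of ``Y`` (shape (n, d))."""
    Y = np.atleast_2d(Y)
    if block.family == "generic":
        return np.asarray(block.logpdf(theta, Y), dtype=float)
    rho = block.rho_value(theta)
    Z = _standardize(block, Y)
    Q, _, s = _bvn_core(Z, rho)
    logdet_sig = float(np.sum(np.log(block.sigmas)))
    if block.family == "bivariate-normal":
        return -LOG2PI - logdet_sig - 0.5 * np.log(s) - Q / (2.0 * s)
    nu = float(block.df)
    k = (nu - 2.0) / nu
    # |S| = k^2 sig1^2 sig2^2 s ;  C_2 = Gamma((nu+2)/2) / (Gamma(nu/2) pi nu)
    logC2 = gammaln((nu + 2.0) / 2.0) - gammaln(nu / 2.0) - np.log(np.pi * nu)
    q = Q / (s * k)
    return logC2 - 0.5 * (2.0 * np.log(k) + 2.0 * logdet_sig + np.log(s)) \
        - 0.5 * (nu + 2.0) * np.log1p(q / nu)


def block_score(block: BlockSpec, theta: dict[str, float], Y: np.ndarray,
                fd_step: float = 1e-6) -> np.ndarray:
    """Unweighted score d log f / d theta_free, shape (n, n_free).

    Analytic for the built-in families; central finite differences for
    generic blocks.
    """
    Y = np.atleast_2d(Y)
    names = block.free_names
    if not names:
        return np.zeros((Y.shape[0], 0))
    if block.family == "generic":
        out = np.empty((Y.shape[0], len(names)))
        for j, nm in enumerate(names):
            hi = dict(theta); hi[nm] = theta[nm] + fd_step
            lo = dict(theta); lo[nm] = theta[nm] - fd_step
            out[:, j] = (block.logpdf(hi, Y) - block.logpdf(lo, Y)) / (2 * fd_step)
        return out
    rho = block.rho_value(theta)
    Z = _standardize(block, Y)
    Q, cross, s = _bvn_core(Z, rho)
    if block.family == "bivariate-normal":
        u = rho / s + (cross * s - rho * Q) / (s * s)
        return u[:, None]
    nu = float(block.df)
    k = (nu - 2.0) / nu
    q = Q / (s * k)
    dq = 2.0 * (rho * Q - cross * s) / (s * s * k)
    u = rho / s - 0.5 * (nu + 2.0) * dq / (nu + q)
    return u[:, None]


# ---------------------------------------------------------------------------
# power integrals (closed forms)
# ---------------------------------------------------------------------------

def block_power_integral(block: BlockSpec, theta: dict[str, float],
                         c: float) -> Optional[float]:
    """Closed form of ``int f(y)^c dy`` over R^2, or None when unavailable.

    Bivariate normal: ``((2 pi s1 s2 sqrt(1-rho^2))^(1-c)) / c``.
    Bivariate t: with ``a = c (nu+2)/2 > 1``,
    ``C_2^c |S|^((1-c)/2) pi nu / (a - 1)``.
    """
    if c <= 0:
        raise ValueError("exponent must be positive")
    if block.family == "generic":
        return None
    rho = block.rho_value(theta)
    s = 1.0 - rho * rho
    sig_prod = float(np.prod(block.sigmas))
    if block.family == "bivariate-normal":
        return float((2.0 * np.pi * sig_prod * np.sqrt(s)) ** (1.0 - c) / c)
    nu = float(block.df)
    a = c * (nu + 2.0) / 2.0
    if a <= 1.0:
        return None  # integral diverges
    k = (nu - 2.0) / nu
    logC2 = gammaln((nu + 2.0) / 2.0) - gammaln(nu / 2.0) - np.log(np.pi * nu)
    logdetS = 2.0 * np.log(k) + 2.0 * np.log(sig_prod) + np.log(s)
    return float(np.exp(c * logC2 + 0.5 * (1.0 - c) * logdetS) * np.pi * nu / (a - 1.0))


# ---------------------------------------------------------------------------
# score-moment integrals  M_j(c) = int f^c u^j dy, j = 0, 1, 2
# ---------------------------------------------------------------------------

def block_moments(block: BlockSpec, theta: dict[str, float], c: float,
                  plan: IntegralPlan) -> tuple[float, np.ndarray, np.ndarray]:
    """Integrals of ``f^c``, ``f^c u`` and ``f^c u u^T`` over the block plane.

    Returns ``(M0, M1, M2)`` with ``M1`` of shape (n_free,) and ``M2`` of
    shape (n_free, n_free).  These are translation invariant: they do not
    depend on the block mean.
    """
    k_free = len(block.free_names)
    if block.family == "bivariate-normal":
        return _normal_moments(block, theta, c, k_free)
    if block.family == "bivariate-t":
        return _t_moments(block, theta, c, k_free, plan)
    return _generic_moments(block, theta, c, k_free, plan)


def _normal_moments(block, theta, c, k_free):
    rho = block.rho_value(theta)
    s = 1.0 - rho * rho
    sig = np.asarray(block.sigmas)
    sig_prod = float(np.prod(sig))
    # substitute y = mu + D L w / sqrt(c): Gaussian weight exp(-|w|^2/2)
    W, wt = gauss_hermite_2d(10)
    L = _chol2(rho)
    Z = (W @ L.T) / np.sqrt(c)
    pref = (2.0 * np.pi * sig_prod * np.sqrt(s)) ** (-c) * sig_prod * np.sqrt(s) / c
    M0 = block_power_integral(block, theta, c)
    if k_free == 0:
        return M0, np.zeros(0), np.zeros((0, 0))
    Q, cross, _ = _bvn_core(Z, rho)
    u = rho / s + (cross * s - rho * Q) / (s * s)
    M1 = pref * float(np.sum(wt * u))
    M2 = pref * float(np.sum(wt * u * u))
    return M0, np.array([M1]), np.array([[M2]])


def _t_moments(block, theta, c, k_free, plan):
    rho = block.rho_value(theta)
    s = 1.0 - rho * rho
    nu = float(block.df)
    k = (nu - 2.0) / nu
    sig = np.asarray(block.sigmas)
    sig_prod = float(np.prod(sig))
    M0 = block_power_integral(block, theta, c)
    if M0 is None:
        raise ValueError(f"power integral of t block diverges at exponent {c}")
    if k_free == 0:
        return M0, np.zeros(0), np.zeros((0, 0))
    # whiten: z = L w  =>  Q/s = |w|^2, dy = sig1 sig2 sqrt(s) dw
    W, wt = tan_map_2d(plan.quad_nodes, plan.tan_scale * np.sqrt(max(nu - 2.0, 1.0)))
    r2 = np.sum(W * W, axis=1)
    L = _chol2(rho)
    Z = W @ L.T
    Q = s * r2
    cross = Z[:, 0] * Z[:, 1]
    q = r2 / k
    dq = 2.0 * (rho * Q - cross * s) / (s * s * k)
    u = rho / s - 0.5 * (nu + 2.0) * dq / (nu + q)
    logC2 = gammaln((nu + 2.0) / 2.0) - gammaln(nu / 2.0) - np.log(np.pi * nu)
    logdetS = 2.0 * np.log(k) + 2.0 * np.log(sig_prod) + np.log(s)
    a = c * (nu + 2.0) / 2.0
    dens = np.exp(c * logC2 - 0.5 * c * logdetS - a * np.log1p(q / nu))
    pref = sig_prod * np.sqrt(s)
    M1 = pref * float(np.sum(wt * dens * u))
    M2 = pref * float(np.sum(wt * dens * u * u))
    return M0, np.array([M1]), np.array([[M2]])


def _generic_moments(block, theta, c, k_free, plan):
    d = len(block.variables)
    if d != 2:
        raise NotImplementedError("generic-block moment integrals support d=2 only")
    center = np.asarray(block.center if block.center is not None else (0.0, 0.0))
    W, wt = tan_map_2d(plan.quad_nodes, plan.tan_scale * 2.0)
    Y = W + center
    logf = block.logpdf(theta, Y)
    dens = np.exp(c * logf)
    M0 = float(np.sum(wt * dens))
    if k_free == 0:
        return M0, np.zeros(0), np.zeros((0, 0))
    U = block_score(block, theta, Y)
    M1 = (wt * dens) @ U
    M2 = (U.T * (wt * dens)) @ U
    return M0, M1, M2


# ---------------------------------------------------------------------------
# inverse-Rosenblatt maps (QMC importance sampling)
# ---------------------------------------------------------------------------

def block_qmc_map(block: BlockSpec, theta: dict[str, float], U: np.ndarray) -> np.ndarray:
    """Map uniforms (n, 2) to block samples via the inverse Rosenblatt map.

    For the t family the conditional distribution of the second coordinate
    given the first is itself a scaled Student t with df + 1 degrees of
    freedom, so both coordinates admit exact inverse-CDF maps.
    """
    if block.family == "generic":
        raise NotImplementedError("generic blocks cannot be QMC-mapped")
    rho = block.rho_value(theta)
    mu = np.asarray(block.mean)
    sig = np.asarray(block.sigmas)
    if block.family == "bivariate-normal":
        Z = ndtri(U)
        L = _chol2(rho)
        return mu + (Z @ L.T) * sig
    nu = float(block.df)
    k = (nu - 2.0) / nu
    S = k * np.array([[sig[0] ** 2, rho * sig[0] * sig[1]],
                      [rho * sig[0] * sig[1], sig[1] ** 2]])
    y1 = mu[0] + np.sqrt(S[0, 0]) * student_t.ppf(U[:, 0], nu)
    d1 = (y1 - mu[0]) ** 2 / S[0, 0]
    loc2 = mu[1] + S[1, 0] / S[0, 0] * (y1 - mu[0])
    scale2 = np.sqrt((nu + d1) / (nu + 1.0) * (S[1, 1] - S[1, 0] ** 2 / S[0, 0]))
    y2 = loc2 + scale2 * student_t.ppf(U[:, 1], nu + 1.0)
    return np.column_stack([y1, y2])
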