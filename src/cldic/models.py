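"""Composite-likelihood models, mixture data generators and data containers.

The two model classes share a parameter-vector contract: ``theta_names``
orders the free parameters, ``bounds`` is a (p, 2) box, and every evaluation
takes the full vector ``theta`` (blocks pick out the entries they read).

:class:`CompositeModel` is a weighted product of blocks; when the blocks
partition the coordinates with unit weights, the composite density is a
proper density on R^m and power integrals factorize over blocks.
:class:`MixtureComposite` is a finite mixture of composite models with
known weights sharing one parameter vector -- the estimation device used
when data come from a mixture of candidate models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .blocks import BlockSpec, block_loglik, block_qmc_map, block_score
from .quadrature import IntegralPlan, sobol_uniforms


class ParameterBoundsError(ValueError):
    """Raised when theta leaves its box."""


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DataSample:
    """An n x m matrix of i.i.d. m-variate observations."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("data must be a 2-D matrix")
        if v.shape[0] < 2:
            raise ValueError("need at least 2 observations")
        if not np.isfinite(v).all():
            raise ValueError("data contain non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        cols = [f"y{j + 1}" for j in range(self.m)]
        pd.DataFrame(self.values, columns=cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DataSample":
        df = pd.read_csv(path)
        return cls(df.to_numpy(dtype=float), provenance=str(path))


def as_matrix(data) -> np.ndarray:
    """Accept a DataSample, DataFrame or array and return the (n, m) matrix."""
    if isinstance(data, DataSample):
        return data.values
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float)
    return np.atleast_2d(np.asarray(data, dtype=float))


# ---------------------------------------------------------------------------
# composite models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositeModel:
    m: int
    blocks: tuple[BlockSpec, ...]
    theta_names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.theta_names) < 1:
            raise ValueError("need at least one free parameter")
        if len(self.bounds) != len(self.theta_names):
            raise ValueError("bounds / theta_names length mismatch")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError("each bound must be a non-empty interval")
        for b in self.blocks:
            if max(b.variables) > self.m:
                raise ValueError("block variable index exceeds dimension m")
            for nm in b.free_names:
                if nm not in self.theta_names:
                    raise ValueError(f"block reads unknown parameter {nm!r}")

    # -- parameter plumbing -------------------------------------------------
    @property
    def p(self) -> int:
        return len(self.theta_names)

    def theta_dict(self, theta: Sequence[float]) -> dict[str, float]:
        theta = np.asarray(theta, dtype=float).ravel()
        if theta.shape[0] != self.p:
            raise ValueError(f"theta must have length {self.p}")
        return dict(zip(self.theta_names, theta))

    def check_theta(self, theta: Sequence[float]) -> np.ndarray:
        theta = np.asarray(theta, dtype=float).ravel()
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        if (theta < lo - 1e-12).any() or (theta > hi + 1e-12).any():
            raise ParameterBoundsError(f"theta {theta} outside bounds {self.bounds}")
        return theta

    def free_index(self, name: str) -> int:
        return self.theta_names.index(name)

    # -- evaluation ---------------------------------------------------------
    def logcl(self, theta: Sequence[float], Y) -> np.ndarray:
        """Composite log-density sum_k w_k l_k(theta, y) at the rows of Y."""
        theta = self.check_theta(theta)
        Y = as_matrix(Y)
        if Y.shape[1] != self.m:
            raise ValueError(f"data dimension {Y.shape[1]} != model m={self.m}")
        td = self.theta_dict(theta)
        out = np.zeros(Y.shape[0])
        for b in self.blocks:
            out += b.weight * block_loglik(b, td, Y[:, b.indices0])
        return out

    def score(self, theta: Sequence[float], Y) -> np.ndarray:
        """Composite score u(theta, y) = d log CL / d theta, shape (n, p)."""
        theta = self.check_theta(theta)
        Y = as_matrix(Y)
        td = self.theta_dict(theta)
        out = np.zeros((Y.shape[0], self.p))
        for b in self.blocks:
            sc = block_score(b, td, Y[:, b.indices0])
            for j, nm in enumerate(b.free_names):
                out[:, self.free_index(nm)] += b.weight * sc[:, j]
        return out

    # -- structure ----------------------------------------------------------
    @property
    def is_partition(self) -> bool:
        """Blocks disjoint, unit weights, covering 1..m: CL is a proper density."""
        idx = [v for b in self.blocks for v in b.variables]
        weights_ok = all(b.weight == 1.0 for b in self.blocks)
        return weights_ok and sorted(idx) == list(range(1, self.m + 1))

    @property
    def is_disjoint(self) -> bool:
        idx = [v for b in self.blocks for v in b.variables]
        return len(idx) == len(set(idx))

    @property
    def covers_all(self) -> bool:
        return set(v for b in self.blocks for v in b.variables) == set(range(1, self.m + 1))

    @property
    def all_builtin(self) -> bool:
        return all(b.family != "generic" for b in self.blocks)


@dataclass(frozen=True)
class MixtureComposite:
    """Known-weight mixture of composite models sharing one parameter vector.

    Zero-weight components are dropped at construction, so the degenerate
    mixtures (weights 0/1) coincide exactly with their surviving component.
    """

    components: tuple[CompositeModel, ...]
    weights: tuple[float, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.components) != len(self.weights):
            raise ValueError("components / weights length mismatch")
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any() or (w > 1).any():
            raise ValueError("mixture weights must lie in [0, 1]")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("mixture weights must sum to 1")
        keep = [(c, wi) for c, wi in zip(self.components, w) if wi > 0.0]
        comps = tuple(c for c, _ in keep)
        ws = tuple(float(wi) for _, wi in keep)
        ref = comps[0]
        for c in comps[1:]:
            if c.theta_names != ref.theta_names or c.m != ref.m:
                raise ValueError("mixture components must share theta_names and m")
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "weights", ws)

    @property
    def m(self) -> int:
        return self.components[0].m

    @property
    def p(self) -> int:
        return self.components[0].p

    @property
    def theta_names(self) -> tuple[str, ...]:
        return self.components[0].theta_names

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        return self.components[0].bounds

    @property
    def is_partition(self) -> bool:
        # a mixture of proper composite densities is itself proper
        return all(c.is_partition for c in self.components)

    @property
    def all_builtin(self) -> bool:
        return all(c.all_builtin for c in self.components)

    def check_theta(self, theta):
        return self.components[0].check_theta(theta)

    def _component_logcl(self, theta, Y) -> np.ndarray:
        return np.stack([c.logcl(theta, Y) for c in self.components])

    def logcl(self, theta: Sequence[float], Y) -> np.ndarray:
        lp = self._component_logcl(theta, as_matrix(Y))
        logw = np.log(self.weights)[:, None]
        return logsumexp(lp + logw, axis=0)

    def score(self, theta: Sequence[float], Y) -> np.ndarray:
        """Score of the mixture: posterior-weighted average of component scores."""
        Y = as_matrix(Y)
        lp = self._component_logcl(theta, Y) + np.log(self.weights)[:, None]
        post = np.exp(lp - logsumexp(lp, axis=0))  # (J, n)
        out = np.zeros((Y.shape[0], self.p))
        for post_j, comp in zip(post, self.components):
            out += post_j[:, None] * comp.score(theta, Y)
        return out


ModelLike = CompositeModel | MixtureComposite


# ---------------------------------------------------------------------------
# frozen QMC importance nodes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QMCNodes:
    """Frozen importance node set: points Y and their proposal log-density."""

    Y: np.ndarray
    logq: np.ndarray


def build_qmc_nodes(model: ModelLike, plan: IntegralPlan,
                    theta_ref: Optional[Sequence[float]] = None) -> QMCNodes:
    """Low-discrepancy importance nodes covering a composite density.

    The proposal is the equal-weight mixture of the model's proper
    component densities evaluated at a fixed reference parameter (the
    midpoint of the box unless ``theta_ref`` is given).  Each component
    receives its own scrambled Sobol stream, mapped to R^m through the
    blockwise inverse Rosenblatt transform.  Equal allocation (rather than
    the mixture weights) keeps every component's region covered even for
    extreme weights.
    """
    comps = model.components if isinstance(model, MixtureComposite) else (model,)
    for c in comps:
        if not (c.is_partition and c.all_builtin):
            raise ValueError("QMC nodes need proper, built-in-block components")
    if theta_ref is None:
        theta_ref = np.array([(lo + hi) / 2.0 for lo, hi in comps[0].bounds])
    theta_ref = np.asarray(theta_ref, dtype=float)
    J = len(comps)
    n_per = int(2 ** np.ceil(np.log2(max(plan.qmc_nodes // J, 256))))
    chunks = []
    for j, comp in enumerate(comps):
        U = sobol_uniforms(n_per, comp.m, plan.qmc_seed + 7919 * j)
        Yj = np.empty((U.shape[0], comp.m))
        td = comp.theta_dict(theta_ref)
        for b in comp.blocks:
            Yj[:, b.indices0] = block_qmc_map(b, td, U[:, b.indices0])
        chunks.append(Yj)
    Y = np.vstack(chunks)
    lp = np.stack([c.logcl(theta_ref, Y) for c in comps])
    logq = logsumexp(lp, axis=0) - np.log(J)
    return QMCNodes(Y=Y, logq=logq)


# ---------------------------------------------------------------------------
# data-generating mixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DGPComponent:
    """One component of the generating mixture: m-variate normal or t.

    ``cov`` is always the *covariance*; for a t component the sampling
    shape matrix is ``((df-2)/df) cov`` so that the component covariance
    equals ``cov`` for any df > 2.
    """

    kind: str
    weight: float
    mean: tuple[float, ...]
    cov: np.ndarray
    df: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "t"):
            raise ValueError("component kind must be 'normal' or 't'")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("component weight must lie in [0, 1]")
        cov = np.asarray(self.cov, dtype=float)
        if not np.allclose(cov, cov.T, atol=1e-12):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("covariance must be positive definite")
        if self.kind == "t" and (self.df is None or self.df <= 2):
            raise ValueError("t components need df > 2")
        object.__setattr__(self, "cov", cov)
        object.__setattr__(self, "mean", tuple(float(x) for x in self.mean))


@dataclass(frozen=True)
class MixtureDGP:
    components: tuple[DGPComponent, ...]

    def __post_init__(self) -> None:
        w = np.array([c.weight for c in self.components])
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("mixture weights must sum to 1")
        m = {np.asarray(c.cov).shape[0] for c in self.components}
        if len(m) != 1:
            raise ValueError("all components must share the dimension m")

    @property
    def m(self) -> int:
        return np.asarray(self.components[0].cov).shape[0]


def _sample_component(comp: DGPComponent, n: int, rng: np.random.Generator) -> np.ndarray:
    mu = np.asarray(comp.mean)
    if comp.kind == "normal":
        L = np.linalg.cholesky(comp.cov)
        return mu + rng.standard_normal((n, len(mu))) @ L.T
    nu = float(comp.df)
    shape = (nu - 2.0) / nu * comp.cov
    L = np.linalg.cholesky(shape)
    z = rng.standard_normal((n, len(mu))) @ L.T
    g = rng.chisquare(nu, size=n)
    return mu + z * np.sqrt(nu / g)[:, None]


def sample(dgp: MixtureDGP, n: int, seed: int | np.random.Generator,
           assignment: str = "random") -> DataSample:
    """Draw n i.i.d. rows from the mixture.

    ``assignment="random"`` draws each row's component from the mixture
    weights (standard mixture semantics); ``"stratified"`` fixes the
    component counts to the exact proportions (largest-remainder rounding),
    the deterministic-split reading of mixing "in the same proportion".
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = np.array([c.weight for c in dgp.components])
    if assignment == "random":
        counts = rng.multinomial(n, w)
    elif assignment == "stratified":
        raw = w * n
        counts = np.floor(raw).astype(int)
        rem = n - counts.sum()
        order = np.argsort(-(raw - np.floor(raw)))
        counts[order[:rem]] += 1
    else:
        raise ValueError("assignment must be 'random' or 'stratified'")
    parts = [_sample_component(c, k, rng)
             for c, k in zip(dgp.components, counts) if k > 0]
    Y = np.vstack(parts)
    rng.shuffle(Y, axis=0)
    tag = f"mixture(seed={seed if not isinstance(seed, np.random.Generator) else 'rng'}, n={n})"
    return DataSample(Y, provenance=tag)
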