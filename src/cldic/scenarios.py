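"""Monte-Carlo model-selection studies on 4-variate normal/t mixtures.

Three study designs are provided.  In each, data are drawn from a mixture
of 4-variate distributions sharing the covariance

    Sigma(rho) = [[1,    rho,  2rho, 2rho],
                  [rho,  1,    2rho, 2rho],
                  [2rho, 2rho, 1,    rho ],
                  [2rho, 2rho, rho,  1   ]],

whose eigenvalues 1 + 5 rho, 1 - 3 rho and 1 - rho (twice) are
non-negative exactly for -1/5 <= rho <= 1/3.  Candidate models are
paired-marginal composite likelihoods on the blocks (y1, y2) and
(y3, y4): within-block correlation rho is the single free parameter; the
cross-block dependence is deliberately ignored by every candidate.

Scenario 1a: normal (means (0, 0, 0.5, 0)) vs t_nu (means
(3.2, 1.5, 0.5, 2)) -- well-separated candidates.  Scenario 1b: the same
contest with nearly equal means ((0, 1.5, 0.5, -0.75) vs (0, 1.5, 0.5, 2),
nu = 5).  Scenario 2: two normals N1/N2 and a t_10 ("MT") in a three-way
contest.  This module doubles as the package's synthetic-data generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .blocks import BlockSpec
from .criterion import select
from .estimation import fit_scenario_parameter
from .models import (CompositeModel, DGPComponent, MixtureComposite,
                     MixtureDGP, build_qmc_nodes, sample)
from .quadrature import DEFAULT_PLAN, IntegralPlan

RHO_MIN, RHO_MAX = -0.2, 1.0 / 3.0
RHO_MARGIN = 1e-3  # keep the search strictly inside the PSD constraint
RHO_BOUNDS = (RHO_MIN + RHO_MARGIN, RHO_MAX - RHO_MARGIN)

MEANS = {
    "1a": {"normal": (0.0, 0.0, 0.5, 0.0), "t": (3.2, 1.5, 0.5, 2.0)},
    "1b": {"normal": (0.0, 1.5, 0.5, -0.75), "t": (0.0, 1.5, 0.5, 2.0)},
    "2": {"n1": (0.0, 0.0, 0.5, 0.0), "n2": (0.0, 1.5, 0.5, 0.0),
          "t": (0.0, 1.5, 0.5, 2.0)},
}
DEFAULT_NU = {"1a": 5.0, "1b": 5.0, "2": 10.0}


def sigma_matrix(rho: float) -> np.ndarray:
    """The common 4x4 covariance; raises outside the PSD range."""
    if not RHO_MIN <= rho <= RHO_MAX:
        raise ValueError(f"rho={rho} violates the PSD constraint "
                         f"[{RHO_MIN}, {RHO_MAX:.4f}]")
    c = 2.0 * rho
    S = np.array([[1.0, rho, c, c],
                  [rho, 1.0, c, c],
                  [c, c, 1.0, rho],
                  [c, c, rho, 1.0]])
    return S


def paired_normal_model(means: Sequence[float], rho_name: str = "rho",
                        sigmas: Sequence[float] = (1.0, 1.0, 1.0, 1.0),
                        bounds: tuple[float, float] = RHO_BOUNDS,
                        name: str = "normal") -> CompositeModel:
    """Composite normal CL on blocks (1,2), (3,4) with shared correlation."""
    blocks = tuple(
        BlockSpec(variables=v, family="bivariate-normal",
                  mean=(means[v[0] - 1], means[v[1] - 1]),
                  sigmas=(sigmas[v[0] - 1], sigmas[v[1] - 1]), rho=rho_name)
        for v in ((1, 2), (3, 4)))
    return CompositeModel(m=4, blocks=blocks, theta_names=(rho_name,),
                          bounds=(bounds,), name=name)


def paired_t_model(means: Sequence[float], nu: float, rho_name: str = "rho",
                   sigmas: Sequence[float] = (1.0, 1.0, 1.0, 1.0),
                   bounds: tuple[float, float] = RHO_BOUNDS,
                   name: str = "t") -> CompositeModel:
    blocks = tuple(
        BlockSpec(variables=v, family="bivariate-t", df=nu,
                  mean=(means[v[0] - 1], means[v[1] - 1]),
                  sigmas=(sigmas[v[0] - 1], sigmas[v[1] - 1]), rho=rho_name)
        for v in ((1, 2), (3, 4)))
    return CompositeModel(m=4, blocks=blocks, theta_names=(rho_name,),
                          bounds=(bounds,), name=name)


def scenario_models(scenario: str, nu: Optional[float] = None) -> dict[str, CompositeModel]:
    """The candidate composite models of a scenario, in selection order."""
    scenario = str(scenario)
    if scenario not in MEANS:
        raise ValueError(f"unknown scenario {scenario!r}; expected 1a, 1b or 2")
    nu = float(nu if nu is not None else DEFAULT_NU[scenario])
    means = MEANS[scenario]
    if scenario in ("1a", "1b"):
        return {"normal": paired_normal_model(means["normal"], name="normal"),
                "t": paired_t_model(means["t"], nu, name="t")}
    return {"N1": paired_normal_model(means["n1"], name="N1"),
            "N2": paired_normal_model(means["n2"], name="N2"),
            "MT": paired_t_model(means["t"], nu, name="MT")}


def scenario_dgp(scenario: str, rho: float, omega: float,
                 lam: Optional[float] = None,
                 nu: Optional[float] = None) -> MixtureDGP:
    """The generating mixture of a scenario at mixing weight(s) omega (, lam)."""
    scenario = str(scenario)
    nu = float(nu if nu is not None else DEFAULT_NU[scenario])
    S = sigma_matrix(rho)
    means = MEANS[scenario]
    if scenario in ("1a", "1b"):
        comps = (DGPComponent("normal", omega, means["normal"], S),
                 DGPComponent("t", 1.0 - omega, means["t"], S, df=nu))
    else:
        if lam is None:
            raise ValueError("scenario 2 needs both omega and lam")
        comps = (DGPComponent("normal", omega, means["n1"], S),
                 DGPComponent("normal", lam, means["n2"], S),
                 DGPComponent("t", 1.0 - omega - lam, means["t"], S, df=nu))
    return MixtureDGP(components=tuple(c for c in comps if c.weight > 0))


def mixture_weights(scenario: str, omega: float, lam: Optional[float]) -> tuple[float, ...]:
    if str(scenario) in ("1a", "1b"):
        return (omega, 1.0 - omega)
    return (omega, lam, 1.0 - omega - lam)


@dataclass(frozen=True)
class ScenarioConfig:
    """Design grid of one simulation study.

    ``omegas`` holds mixing weights: floats for the two-component
    scenarios, (omega, lam) pairs for scenario 2.  Replication r of cell
    (n, omega, alpha) uses the seed stream derived from
    (base_seed, scenario, n, omega, alpha, r), so any cell can be re-run
    in isolation.
    """

    scenario: str
    n_values: tuple[int, ...] = (100,)
    omegas: tuple = (0.0, 0.5, 1.0)
    alphas: tuple[float, ...] = (0.0, 0.3)
    rho0: float = -0.15
    nu: Optional[float] = None
    reps: int = 200
    base_seed: int = 42
    estimation_mode: str = "mixture"
    assignment: str = "random"
    plan: IntegralPlan = DEFAULT_PLAN

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not RHO_MIN < self.rho0 < RHO_MAX:
            raise ValueError("rho0 must lie strictly inside the PSD range")
        for a in self.alphas:
            if a < 0:
                raise ValueError("alpha values must be non-negative")
        for w in self.omegas:
            pair = w if isinstance(w, tuple) else (w,)
            if any(not 0.0 <= x <= 1.0 for x in pair) or sum(pair) > 1.0 + 1e-12:
                raise ValueError(f"invalid mixing weight(s) {w}")


@dataclass(frozen=True)
class SelectionCountsTable:
    """Machine-readable selection counts: one row per (cell, candidate)."""

    counts: pd.DataFrame
    reps: int
    base_seed: int

    def cell(self, n: int, omega, alpha: float) -> pd.DataFrame:
        df = self.counts
        ok, lk = _omega_key(omega)
        lam_match = df.lam.isna() if np.isnan(lk) else np.isclose(df.lam, lk)
        return df[(df.n == n) & np.isclose(df.omega, ok) & lam_match
                  & np.isclose(df.alpha, alpha)]


def _omega_key(omega) -> tuple[float, float]:
    if isinstance(omega, tuple):
        return float(omega[0]), float(omega[1])
    return float(omega), np.nan


def _cell_seed(base_seed: int, scenario: str, n: int, omega, alpha: float,
               rep: int) -> np.random.SeedSequence:
    ok, lk = _omega_key(omega)
    lk = 0.0 if np.isnan(lk) else lk
    ints = (int(base_seed), {"1a": 1, "1b": 2, "2": 3}[str(scenario)], int(n),
            int(round(1000 * ok)), int(round(1000 * lk)),
            int(round(1000 * alpha)), int(rep))
    return np.random.SeedSequence(ints)


def run_cell(scenario: str, n: int, omega, alpha: float, reps: int,
             base_seed: int, rho0: float = -0.15, nu: Optional[float] = None,
             estimation_mode: str = "mixture", assignment: str = "random",
             plan: IntegralPlan = DEFAULT_PLAN) -> dict:
    """Selection counts for one (n, omega, alpha) design cell."""
    ok, lk = _omega_key(omega)
    lam = None if np.isnan(lk) else lk
    candidates = scenario_models(scenario, nu)
    dgp = scenario_dgp(scenario, rho0, ok, lam, nu)
    weights = mixture_weights(scenario, ok, lam)
    mix = MixtureComposite(components=tuple(candidates.values()),
                           weights=weights)
    # one frozen node set per cell: reused by every replication's objective
    nodes = None
    if alpha > 0 and len(mix.components) > 1:
        nodes = build_qmc_nodes(mix, plan)
    counts = {name: 0 for name in candidates}
    failures = 0
    for rep in range(reps):
        ss = _cell_seed(base_seed, scenario, n, omega, alpha, rep)
        rng = np.random.default_rng(ss)
        try:
            data = sample(dgp, n, rng, assignment=assignment)
            if estimation_mode == "mixture":
                fit = fit_scenario_parameter(mix, data, alpha, "mixture",
                                             plan, nodes=nodes)
                res = select(candidates, data, alpha, estimation="plugin",
                             theta_hat=fit.theta, plan=plan)
            else:
                res = select(candidates, data, alpha,
                             estimation="per-candidate", plan=plan)
            counts[res.selected_name] += 1
        except Exception:  # noqa: BLE001 - tallied, never silently dropped
            failures += 1
    return {"scenario": scenario, "n": n, "omega": ok, "lam": lk,
            "alpha": alpha, "counts": counts, "failures": failures,
            "reps": reps}


def run_scenario(config: ScenarioConfig) -> SelectionCountsTable:
    """Run the full design grid of a scenario and tabulate selections."""
    rows = []
    for n in config.n_values:
        for omega in config.omegas:
            for alpha in config.alphas:
                cell = run_cell(config.scenario, n, omega, alpha, config.reps,
                                config.base_seed, config.rho0, config.nu,
                                config.estimation_mode, config.assignment,
                                config.plan)
                for cand, cnt in cell["counts"].items():
                    rows.append({"scenario": config.scenario, "n": n,
                                 "omega": cell["omega"], "lam": cell["lam"],
                                 "alpha": alpha, "candidate": cand,
                                 "count": cnt, "reps": config.reps,
                                 "failures": cell["failures"]})
    return SelectionCountsTable(counts=pd.DataFrame(rows), reps=config.reps,
                                base_seed=config.base_seed)
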