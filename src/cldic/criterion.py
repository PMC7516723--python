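"""The composite-likelihood divergence information criterion (CLDIC).

For candidate model M_k with fitted parameter theta_hat,

    CLDIC_alpha(M_k) = W_{n,alpha}(theta_hat)
                       + (alpha + 1)/n * trace(J_alpha H_alpha^{-1}),

evaluated at theta_hat; the candidate with the smallest value is selected.
At alpha = 0 this is the composite Akaike criterion (CAIC): mean negative
composite log-likelihood plus trace(J H^{-1})/n.

Two estimation modes are exposed: a plug-in mode where one theta_hat
(typically fitted under the known-weight mixture of the candidates) is
shared by every candidate, and a per-candidate mode where each candidate
is fitted under its own composite likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .divergence import wn
from .estimation import cmdpde_fit, fit_scenario_parameter
from .models import CompositeModel, MixtureComposite, ModelLike, as_matrix
from .quadrature import DEFAULT_PLAN, IntegralPlan
from .sandwich import penalty_trace, sandwich_matrices

TIE_TOL = 1e-10


@dataclass(frozen=True)
class CandidateRecord:
    name: str
    theta: Optional[np.ndarray]
    wn_value: float
    penalty: float
    cldic: float
    failed: bool = False
    error: str = ""


@dataclass(frozen=True)
class CriterionResult:
    records: tuple[CandidateRecord, ...]
    selected_index: int
    alpha: float
    tie: bool

    @property
    def selected_name(self) -> str:
        return self.records[self.selected_index].name

    def table(self):
        import pandas as pd
        return pd.DataFrame([
            {"model": r.name, "wn": r.wn_value, "penalty": r.penalty,
             "cldic": r.cldic, "failed": r.failed}
            for r in self.records])


def cldic(model: ModelLike, data, alpha: float,
          theta_hat: Optional[Sequence[float]] = None,
          plan: IntegralPlan = DEFAULT_PLAN,
          name: str = "") -> CandidateRecord:
    """Evaluate CLDIC_alpha for one candidate.

    ``theta_hat`` given: plug-in evaluation at that parameter.  Absent:
    the candidate is fitted internally by CMDPDE first.
    """
    Y = as_matrix(data)
    n = Y.shape[0]
    if theta_hat is None:
        theta_hat = cmdpde_fit(model, Y, alpha, plan).theta
    theta_hat = model.check_theta(theta_hat)
    if n < model.p + 1:
        warnings.warn(f"n={n} too small for a stable trace penalty (p={model.p})")
    w = wn(model, theta_hat, Y, alpha, plan)
    sw = sandwich_matrices(model, theta_hat, alpha, plan)
    pen = penalty_trace(sw, n)
    return CandidateRecord(name=name or getattr(model, "name", "") or "model",
                           theta=np.asarray(theta_hat), wn_value=w,
                           penalty=pen, cldic=w + pen)


def select(candidates, data, alpha: float,
           estimation: str = "mixture",
           weights: Optional[Sequence[float]] = None,
           theta_hat: Optional[Sequence[float]] = None,
           plan: IntegralPlan = DEFAULT_PLAN,
           mixture_nodes=None) -> CriterionResult:
    """Evaluate CLDIC_alpha for every candidate and pick the minimizer.

    Parameters
    ----------
    candidates:
        dict name -> model, or a sequence of models (named by position).
    estimation:
        ``"mixture"``: fit one shared theta under the known-weight mixture
        of the candidates (requires ``weights``) and plug it into every
        candidate.  ``"per-candidate"``: fit each candidate separately.
        ``"plugin"``: use the supplied ``theta_hat`` for every candidate.
    """
    if isinstance(candidates, dict):
        names = list(candidates)
        models = list(candidates.values())
    else:
        models = list(candidates)
        names = [getattr(mdl, "name", "") or f"M{i + 1}" for i, mdl in enumerate(models)]
    if len(models) < 2:
        raise ValueError("need at least two candidate models")
    dims = {mdl.m for mdl in models}
    if len(dims) != 1:
        raise ValueError("candidates must share the data dimension m")
    Y = as_matrix(data)

    shared_theta = None
    if estimation == "plugin":
        if theta_hat is None:
            raise ValueError("plugin mode needs theta_hat")
        shared_theta = np.asarray(theta_hat, dtype=float)
    elif estimation == "mixture":
        if weights is None:
            raise ValueError("mixture mode needs the known mixture weights")
        mix = MixtureComposite(components=tuple(models), weights=tuple(weights))
        fit = fit_scenario_parameter(mix, Y, alpha, mode="mixture", plan=plan,
                                     nodes=mixture_nodes)
        shared_theta = fit.theta
    elif estimation != "per-candidate":
        raise ValueError("estimation must be 'mixture', 'per-candidate' or 'plugin'")

    records = []
    for nm, mdl in zip(names, models):
        try:
            records.append(cldic(mdl, Y, alpha, theta_hat=shared_theta,
                                 plan=plan, name=nm))
        except Exception as exc:  # noqa: BLE001 - failures are data, not crashes
            records.append(CandidateRecord(name=nm, theta=None,
                                           wn_value=np.nan, penalty=np.nan,
                                           cldic=np.inf, failed=True,
                                           error=repr(exc)))
    ok = [r for r in records if not r.failed]
    if len(ok) < 2:
        raise RuntimeError(
            f"fewer than two candidates evaluated successfully: "
            f"{[r.error for r in records if r.failed]}")
    values = np.array([r.cldic for r in records])
    selected = int(np.argmin(values))  # argmin takes the first index on ties
    finite = values[np.isfinite(values)]
    tie = bool(np.sum(np.abs(finite - values[selected]) <= TIE_TOL) > 1)
    return CriterionResult(records=tuple(records), selected_index=selected,
                           alpha=float(alpha), tie=tie)
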