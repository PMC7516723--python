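"""Structured-config parsing: model specifications and run configurations.

Model files (YAML or JSON, both parsed by the YAML loader) describe a
composite model::

    m: 4
    theta:
      rho: [-0.199, 0.3323]
    blocks:
      - family: bivariate-normal
        variables: [1, 2]        # 1-based, as written in the model
        mean: [0.0, 0.0]
        sigmas: [1.0, 1.0]
        rho: rho                 # a name -> free; a number -> fixed
      - family: bivariate-t
        variables: [3, 4]
        df: 5
        ...

Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .blocks import BlockSpec
from .models import CompositeModel
from .quadrature import IntegralPlan

_BLOCK_KEYS = {"family", "variables", "mean", "sigmas", "rho", "df", "weight"}
_MODEL_KEYS = {"m", "theta", "blocks", "name"}
_RUN_KEYS = {"scenario", "n_values", "omegas", "alphas", "rho0", "nu", "reps",
             "seed", "estimation_mode", "assignment", "plan"}
_PLAN_KEYS = {"method", "quad_nodes", "tan_scale", "qmc_nodes", "qmc_seed",
              "tolerance"}


class ConfigError(ValueError):
    pass


def _check_keys(d: dict, allowed: set, what: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown {what} keys: {sorted(unknown)}")


def model_from_dict(spec: dict) -> CompositeModel:
    _check_keys(spec, _MODEL_KEYS, "model")
    for key in ("m", "theta", "blocks"):
        if key not in spec:
            raise ConfigError(f"model config missing {key!r}")
    theta = spec["theta"]
    names = tuple(theta)
    bounds = []
    for nm in names:
        b = theta[nm]
        if not (isinstance(b, (list, tuple)) and len(b) == 2):
            raise ConfigError(f"theta {nm!r} bounds must be [lo, hi]")
        bounds.append((float(b[0]), float(b[1])))
    blocks = []
    for bd in spec["blocks"]:
        _check_keys(bd, _BLOCK_KEYS, "block")
        kwargs = dict(bd)
        kwargs["variables"] = tuple(int(v) for v in kwargs["variables"])
        for key in ("mean", "sigmas"):
            if key in kwargs:
                kwargs[key] = tuple(float(x) for x in kwargs[key])
        blocks.append(BlockSpec(**kwargs))
    return CompositeModel(m=int(spec["m"]), blocks=tuple(blocks),
                          theta_names=names, bounds=tuple(bounds),
                          name=str(spec.get("name", "")))


def model_to_dict(model: CompositeModel) -> dict:
    return {
        "m": model.m,
        "name": model.name,
        "theta": {nm: [float(lo), float(hi)]
                  for nm, (lo, hi) in zip(model.theta_names, model.bounds)},
        "blocks": [
            {k: v for k, v in {
                "family": b.family, "variables": list(b.variables),
                "mean": list(b.mean), "sigmas": list(b.sigmas),
                "rho": b.rho, "df": b.df, "weight": b.weight,
            }.items() if v not in ((), None)}
            for b in model.blocks],
    }


def load_model(path: str | Path) -> CompositeModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))


def save_model(model: CompositeModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=True)


@dataclass(frozen=True)
class RunConfig:
    """A validated simulation run: scenario id plus design-grid overrides."""

    scenario: str
    n_values: tuple[int, ...] = (100,)
    omegas: tuple = (0.0, 0.5, 1.0)
    alphas: tuple[float, ...] = (0.0, 0.3)
    rho0: float = -0.15
    nu: float | None = None
    reps: int = 200
    seed: int = 42
    estimation_mode: str = "mixture"
    assignment: str = "random"
    plan: IntegralPlan = IntegralPlan()

    def __post_init__(self) -> None:
        for a in self.alphas:
            if a < 0:
                raise ConfigError(f"alpha must be non-negative, got {a}")


def run_config_from_dict(d: dict) -> RunConfig:
    _check_keys(d, _RUN_KEYS, "run")
    if "scenario" not in d:
        raise ConfigError("run config missing 'scenario'")
    kw = dict(d)
    kw["scenario"] = str(kw["scenario"])
    if "plan" in kw:
        _check_keys(kw["plan"], _PLAN_KEYS, "plan")
        kw["plan"] = IntegralPlan(**kw["plan"])
    for key in ("n_values", "alphas"):
        if key in kw:
            kw[key] = tuple(kw[key])
    if "omegas" in kw:
        kw["omegas"] = tuple(tuple(w) if isinstance(w, (list, tuple)) else float(w)
                             for w in kw["omegas"])
    return RunConfig(**kw)


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return run_config_from_dict(yaml.safe_load(fh))


def run_config_to_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d["plan"] = asdict(cfg.plan)
    d["n_values"] = list(cfg.n_values)
    d["alphas"] = list(cfg.alphas)
    d["omegas"] = [list(w) if isinstance(w, tuple) else w for w in cfg.omegas]
    return d
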