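"""Scenario fixtures, parameter sampling, configuration and file I/O.

Every analysis in the package runs from synthetic inputs: named
parameter scenarios (the canonical oscillatory set and companions in
the stable, near-onset and neutral regimes), or seeded random parameter
draws filtered by dynamical regime.  This module also owns the on-disk
formats: trajectory CSV tables, JSON reports, and JSON/YAML run
configurations for the command-line interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .dynamics import Trajectory, derive_observables
from .equilibria import coexistence_equilibrium
from .model import AggregationRule, ModelParams, State

__all__ = [
    "Scenario",
    "canonical_scenarios",
    "get_scenario",
    "sample_params",
    "trajectory_columns",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_json",
    "load_config",
    "params_from_config",
]

#: documented column order of trajectory CSV files
trajectory_columns = [
    "t", "R", "N", "x", "p_F", "p_S", "p_bar", "frac_grouped",
    "n_fast_alone", "n_fast_grouped", "n_slow_alone", "n_slow_grouped",
]


@dataclass(frozen=True)
class Scenario:
    """A named, fully deterministic simulation setup."""

    name: str
    params: ModelParams
    description: str = ""
    init: Optional[State] = None  # None: perturbed coexistence equilibrium
    t_span: tuple[float, float] = (0.0, 200.0)
    seed: int = 0  # seed of the initial perturbation vector
    neutral_x: Optional[float] = None  # fixed composition, neutral submodel only


def canonical_scenarios() -> list[Scenario]:
    """The built-in scenario set.

    * ``canonical_lc`` — the printed oscillatory parameter set
      ``(r, K, d, lambda_F, lambda_S) = (1, 1, 1, 28, 16)``;
    * ``low_exploitation_sc`` — same ``lambda_F`` with exploitation
      reduced to ``lambda_S = 10``, inside the stable-coexistence
      regime (verified by the eigenvalue check at construction);
    * ``near_hopf_lc`` — ``lambda_S = 14``, just above the oscillation
      onset at ``lambda_F = 28``;
    * ``neutral`` — the fixed-composition ecological submodel at the
      canonical parameters with the fast fraction frozen at 0.5.
    """
    base = ModelParams()
    return [
        Scenario(
            "canonical_lc",
            base,
            "canonical oscillatory regime: life-like aggregation cycles",
        ),
        Scenario(
            "low_exploitation_sc",
            base.replace(lambda_S=10.0),
            "stable coexistence of fast and slow cells at low exploitation",
        ),
        Scenario(
            "near_hopf_lc",
            base.replace(lambda_S=14.0),
            "small-amplitude cycles just above the oscillation onset",
            t_span=(0.0, 2000.0),
        ),
        Scenario(
            "neutral",
            base,
            "purely ecological submodel with the fast fraction frozen",
            neutral_x=0.5,
        ),
    ]


def get_scenario(name: str) -> Scenario:
    for sc in canonical_scenarios():
        if sc.name == name:
            return sc
    known = ", ".join(s.name for s in canonical_scenarios())
    raise KeyError(f"unknown scenario {name!r}; known scenarios: {known}")


_DEFAULT_BOUNDS = {
    "r": (0.5, 2.0),
    "K": (0.5, 2.0),
    "d": (0.5, 2.0),
    "lambda_F": (8.0, 40.0),
    "lambda_S": (2.0, 30.0),
}


def sample_params(
    region: str,
    n: int,
    seed: int,
    *,
    bounds: Optional[dict] = None,
    max_rejections: int = 20000,
) -> list[ModelParams]:
    """Seeded random parameter draws verified to lie in ``region``.

    ``region`` is ``"SC"`` (interior equilibrium exists and is stable)
    or ``"LC"`` (exists and is unstable).  Draws are uniform over the
    given bounds and rejected until the eigenvalue check confirms the
    requested regime; raises after ``max_rejections`` failures.
    """
    if region not in ("SC", "LC"):
        raise ValueError("region must be 'SC' or 'LC'")
    if n < 1:
        raise ValueError("n must be >= 1")
    b = dict(_DEFAULT_BOUNDS)
    b.update(bounds or {})
    rng = np.random.default_rng(seed)
    out: list[ModelParams] = []
    rejections = 0
    while len(out) < n:
        if rejections > max_rejections:
            raise RuntimeError(
                f"could not find {n} parameter sets in region {region} "
                f"within {max_rejections} rejections"
            )
        draw = {k: float(rng.uniform(*b[k])) for k in _DEFAULT_BOUNDS}
        try:
            params = ModelParams(**draw)
        except ValueError:
            rejections += 1
            continue
        rep = coexistence_equilibrium(params)
        wanted = "unstable" if region == "LC" else "stable"
        if rep.exists and rep.stability == wanted:
            out.append(params)
        else:
            rejections += 1
    return out


# ---------------------------------------------------------------------------
# file formats


def write_trajectory_csv(traj: Trajectory, path) -> pd.DataFrame:
    """Write the 12-column observable table for a trajectory; returns it."""
    df = derive_observables(traj)[trajectory_columns]
    df.to_csv(path, index=False, float_format="%.12g")
    return df


def read_trajectory_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in trajectory_columns if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file {path} missing columns {missing}")
    return df


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# configuration


def load_config(path) -> dict:
    """Load a JSON or YAML run configuration (dispatch on extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must contain a mapping")
    return cfg


_MODEL_KEYS = {"r", "K", "d", "lambda_F", "lambda_S", "aggregation_kind", "alone_scale"}


def params_from_config(model_cfg: dict) -> ModelParams:
    """Build :class:`ModelParams` from a ``[model]`` config section."""
    unknown = set(model_cfg) - _MODEL_KEYS
    if unknown:
        raise ValueError(f"unknown model config keys: {sorted(unknown)}")
    kwargs = {k: v for k, v in model_cfg.items() if k in ModelParams.__annotations__}
    kind = model_cfg.get("aggregation_kind", "linear")
    scale = model_cfg.get("alone_scale", 1.0)
    kwargs["aggregation"] = AggregationRule(kind=kind, alone_scale=float(scale))
    return ModelParams(**kwargs)
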