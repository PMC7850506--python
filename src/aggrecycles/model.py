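"""Core eco-evolutionary model: parameters, payoffs and ODE right-hand sides.

The model couples three processes on a single nondimensional timescale:

* logistic growth of a shared resource of density ``R`` (maximum growth
  rate ``r``, carrying capacity ``K``), consumed at unit encounter rate
  by every cell;
* demography of a consumer population of size ``N`` with common death
  rate ``d`` and a per-capita birth rate equal to the mean reproductive
  payoff times the resource density;
* replicator dynamics of the fraction ``x`` of fast-moving cells, the
  heritable motility trait.

Cells partition between a solitary and an aggregated state as a function
of resource availability: the probability of remaining solitary increases
with ``R`` (all cells are solitary at carrying capacity, all aggregate
when the resource is depleted).  Fast cells earn payoff only while
solitary (efficient local foraging, coefficient ``lambda_F``); slow cells
earn payoff only inside groups, by exploiting the collective transport
fuelled by the fast cells present there (coefficient ``lambda_S``).  This
trade-off makes slow cells social cheaters in a public-goods sense, and
couples the ecological and evolutionary dynamics.

The module also carries two companion systems: a fixed-composition
("neutral") two-variable submodel used for purely ecological stability
analysis, and a three-strategy (fast / resident slow / mutant slow)
five-variable system used for invasion analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

__all__ = [
    "AggregationRule",
    "ModelParams",
    "State",
    "PayoffBundle",
    "ThreeStrategyState",
    "probability_alone",
    "payoffs",
    "mean_payoff",
    "rhs",
    "rhs_neutral",
    "rhs_three_strategy",
    "SIMPLEX_TOL",
]

#: tolerance on the frequency simplex for the three-strategy system
SIMPLEX_TOL = 1e-6


@dataclass(frozen=True)
class AggregationRule:
    """How the solitary/grouped partition responds to resource density.

    ``kind='linear'``
        probability of remaining solitary is ``R/K``: all cells solitary
        at carrying capacity, all grouped when the resource is depleted.
    ``kind='bounded'``
        probability is ``a * R/K`` with ``a = alone_scale`` in ``(0, 1]``;
        even a resource at carrying capacity leaves a fraction ``1 - a``
        of the population inside groups.  The linear rule is the
        special case ``a = 1``.
    """

    kind: str = "linear"
    alone_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "bounded"):
            raise ValueError(f"unknown aggregation rule kind {self.kind!r}")
        if not 0.0 < self.alone_scale <= 1.0:
            raise ValueError("alone_scale must lie in (0, 1]")
        if self.kind == "linear" and self.alone_scale != 1.0:
            raise ValueError("the linear rule fixes alone_scale = 1")


LINEAR_RULE = AggregationRule()


@dataclass(frozen=True)
class ModelParams:
    """Scalar parameters of the eco-evolutionary model.

    Attributes
    ----------
    r : float
        Resource maximum growth rate (per unit time).
    K : float
        Resource carrying capacity (resource-density units).
    d : float
        Consumer death rate (per unit time), identical for both types.
    lambda_F : float
        Fast-cell solitary-feeding payoff coefficient (dimensionless).
    lambda_S : float
        Slow-cell within-group exploitation payoff coefficient
        (dimensionless); the evolvable trait in the adaptive-dynamics
        analysis.
    aggregation : AggregationRule
        Resource-dependence of the solitary/grouped partition.

    Defaults are the canonical oscillatory parameter set
    ``(r, K, d, lambda_F, lambda_S) = (1, 1, 1, 28, 16)``.
    """

    r: float = 1.0
    K: float = 1.0
    d: float = 1.0
    lambda_F: float = 28.0
    lambda_S: float = 16.0
    aggregation: AggregationRule = LINEAR_RULE

    def __post_init__(self) -> None:
        for name in ("r", "K", "d", "lambda_F", "lambda_S"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be positive and finite, got {value}")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class State:
    """A point ``(R, N, x)`` in phase space.

    ``R`` is resource density, ``N`` total cell population size and
    ``x`` the frequency of fast-moving cells.  Construction accepts any
    finite values (equilibrium candidates may fall outside the
    admissible domain); :meth:`validate` enforces the model domain
    ``R >= 0``, ``N >= 0``, ``0 <= x <= 1``.
    """

    R: float
    N: float
    x: float

    def as_array(self) -> np.ndarray:
        return np.array([self.R, self.N, self.x], dtype=float)

    @property
    def is_admissible(self) -> bool:
        return self.R >= 0 and self.N >= 0 and 0.0 <= self.x <= 1.0

    def validate(self) -> "State":
        if not all(np.isfinite(v) for v in (self.R, self.N, self.x)):
            raise ValueError(f"non-finite state {self}")
        if not self.is_admissible:
            raise ValueError(
                f"state outside model domain (need R>=0, N>=0, 0<=x<=1): {self}"
            )
        return self


@dataclass(frozen=True)
class PayoffBundle:
    """Per-type and mean reproductive payoffs at a given ``(x, R)``."""

    p_F: float
    p_S: float
    p_bar: float


@dataclass(frozen=True)
class ThreeStrategyState:
    """State of the fast / resident-slow / mutant-slow system.

    The three frequencies live on the simplex ``x_F + x_Sr + x_Sm = 1``
    (checked to :data:`SIMPLEX_TOL` at construction).
    """

    R: float
    N: float
    x_F: float
    x_Sr: float
    x_Sm: float

    def __post_init__(self) -> None:
        total = self.x_F + self.x_Sr + self.x_Sm
        if abs(total - 1.0) > SIMPLEX_TOL:
            raise ValueError(f"frequencies must sum to 1, got {total}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.R, self.N, self.x_F, self.x_Sr, self.x_Sm], dtype=float
        )


StateLike = Union[State, Sequence[float], np.ndarray]


def _unpack3(state: StateLike) -> tuple[float, float, float]:
    if isinstance(state, State):
        return state.R, state.N, state.x
    R, N, x = state
    return float(R), float(N), float(x)


def probability_alone(R, params: ModelParams):
    """Probability that a cell remains solitary at resource density ``R``.

    Vectorised over ``R``.  Linear rule: ``min(R/K, 1)``; bounded rule:
    ``a*R/K`` clipped to ``[0, 1]``.  Values of ``R`` above ``K``
    (transient overshoot) are clipped to probability 1.
    """
    R_arr = np.asarray(R, dtype=float)
    if np.any(R_arr < 0):
        raise ValueError("resource density must be non-negative")
    p = np.clip(params.aggregation.alone_scale * R_arr / params.K, 0.0, 1.0)
    return float(p) if np.ndim(R) == 0 else p


def payoffs(x, R, params: ModelParams) -> PayoffBundle:
    """Per-type payoffs and the population mean payoff at ``(x, R)``.

    Fast cells earn ``P(alone) * lambda_F``: they reproduce only while
    solitary.  Slow cells earn ``x * (1 - P(alone)) * lambda_S``: their
    benefit scales with the chance of being grouped and with the
    frequency of fast cells available to exploit.  Vectorised over
    matching shapes of ``x`` and ``R``.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0) or np.any(x_arr > 1):
        raise ValueError("fast-cell frequency must lie in [0, 1]")
    pi = probability_alone(R, params)
    p_F = pi * params.lambda_F
    p_S = x_arr * (1.0 - np.asarray(pi)) * params.lambda_S
    p_bar = x_arr * p_F + (1.0 - x_arr) * p_S
    if np.ndim(x) == 0 and np.ndim(R) == 0:
        return PayoffBundle(float(p_F), float(p_S), float(p_bar))
    return PayoffBundle(np.asarray(p_F), np.asarray(p_S), np.asarray(p_bar))


def mean_payoff(x, R, params: ModelParams):
    """Mean payoff ``p_bar(x, R)`` (convenience wrapper over :func:`payoffs`)."""
    return payoffs(x, R, params).p_bar


def rhs(state: StateLike, params: ModelParams) -> np.ndarray:
    """Time derivative ``(dR/dt, dN/dt, dx/dt)`` of the full model.

    ``dR/dt = R [r (1 - R/K) - N]``;
    ``dN/dt = N [p_bar R - d]``;
    ``dx/dt = x (1 - x) R [p_F - p_S]``.

    No domain validation is performed here (adaptive integrators probe
    slightly outside the domain); the partition probability is clipped
    to ``[0, 1]`` internally.
    """
    R, N, x = _unpack3(state)
    pi = params.aggregation.alone_scale * R / params.K
    pi = 0.0 if pi < 0.0 else (1.0 if pi > 1.0 else pi)
    p_F = pi * params.lambda_F
    p_S = x * (1.0 - pi) * params.lambda_S
    p_bar = x * p_F + (1.0 - x) * p_S
    return np.array(
        [
            R * (params.r * (1.0 - R / params.K) - N),
            N * (p_bar * R - params.d),
            x * (1.0 - x) * R * (p_F - p_S),
        ]
    )


def rhs_neutral(R: float, N: float, x_fixed: float, params: ModelParams) -> np.ndarray:
    """Right-hand side of the fixed-composition ecological submodel.

    When both types are neutral the fast-cell fraction stays at
    ``x_fixed`` and only the resource and demographic equations remain,
    with the mean payoff evaluated at that frozen composition.
    """
    if not 0.0 <= x_fixed <= 1.0:
        raise ValueError("x_fixed must lie in [0, 1]")
    pi = params.aggregation.alone_scale * R / params.K
    pi = 0.0 if pi < 0.0 else (1.0 if pi > 1.0 else pi)
    p_F = pi * params.lambda_F
    p_S = x_fixed * (1.0 - pi) * params.lambda_S
    p_bar = x_fixed * p_F + (1.0 - x_fixed) * p_S
    return np.array(
        [
            R * (params.r * (1.0 - R / params.K) - N),
            N * (p_bar * R - params.d),
        ]
    )


def rhs_three_strategy(
    state,
    params: ModelParams,
    lambda_S_mut: float,
    *,
    simplex_tol: float = SIMPLEX_TOL,
) -> np.ndarray:
    """Right-hand side of the fast / resident-slow / mutant-slow system.

    The two slow types differ only in their exploitation coefficient;
    both draw their group benefit from the same fast fraction ``x_F``.
    Each frequency follows a replicator term ``x_i R (p_i - p_bar)``,
    which conserves the simplex exactly in continuous time.  A
    frequency-sum violation beyond ``simplex_tol`` raises.
    """
    if lambda_S_mut <= 0:
        raise ValueError("lambda_S_mut must be positive")
    if isinstance(state, ThreeStrategyState):
        R, N, x_F, x_Sr, x_Sm = state.as_array()
    else:
        R, N, x_F, x_Sr, x_Sm = (float(v) for v in state)
    total = x_F + x_Sr + x_Sm
    if abs(total - 1.0) > simplex_tol:
        raise ValueError(f"frequencies must sum to 1 (tol {simplex_tol}), got {total}")
    pi = params.aggregation.alone_scale * R / params.K
    pi = 0.0 if pi < 0.0 else (1.0 if pi > 1.0 else pi)
    p_F = pi * params.lambda_F
    shared = x_F * (1.0 - pi)  # group benefit per unit exploitation coefficient
    p_Sr = shared * params.lambda_S
    p_Sm = shared * lambda_S_mut
    p_bar = x_F * p_F + x_Sr * p_Sr + x_Sm * p_Sm
    return np.array(
        [
            R * (params.r * (1.0 - R / params.K) - N),
            N * (p_bar * R - params.d),
            x_F * R * (p_F - p_bar),
            x_Sr * R * (p_Sr - p_bar),
            x_Sm * R * (p_Sm - p_bar),
        ]
    )
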