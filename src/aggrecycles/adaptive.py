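"""Invasion fitness and trait-substitution evolution of exploitation.

The exploitation coefficient ``lambda_S`` of the slow (cheater) type is
treated as a continuously evolving trait.  A rare mutant with trait
``lambda_S_mut`` in a resident population with trait ``lambda_S_res``
grows (in frequency) at the transverse rate ``R (p_mut - p_bar)``
evaluated on the resident attractor.  Three estimators are provided:

* ``analytic``: at a stable coexistence equilibrium the average rate
  reduces to the closed form ``S = d (lambda_S_mut - lambda_S_res) /
  lambda_S_res``;
* ``cycle_average``: on a resident limit cycle, the Floquet-type
  cycle average ``S = (1/T) \\oint R (p_mut - p_bar) dt``;
* ``direct_sim``: the slope of log mutant frequency in the full
  five-variable fast / resident-slow / mutant-slow system, sampled at
  integer multiples of the resident period while the mutant is rare.

Trait substitution iterates rare-mutant invasions with a fixed trait
increment, substituting the resident whenever fitness is positive, and
records the passage from the stable-coexistence (SC) regime into the
oscillatory (LC) regime.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import simpson, solve_ivp

from .dynamics import (
    DEFAULT_ATOL,
    DEFAULT_METHOD,
    DEFAULT_RTOL,
    IntegrationError,
    LimitCycleSummary,
    find_limit_cycle,
)
from .equilibria import coexistence_equilibrium
from .model import ModelParams, State, payoffs, probability_alone, rhs_three_strategy

__all__ = [
    "InvasionResult",
    "EvolutionTrace",
    "classify_regime",
    "invasion_fitness_equilibrium",
    "invasion_fitness_cycle",
    "invasion_fitness_direct",
    "trait_substitution",
    "reciprocal_scaling_check",
]

logger = logging.getLogger(__name__)

#: initial mutant share of the slow subpopulation in direct simulations
RARE_FREQ = 1e-6
#: the mutant is considered rare while its frequency stays below this
#: multiple of its initial value
RARITY_CEILING = 100.0


@dataclass(frozen=True)
class InvasionResult:
    """Invasion fitness of one mutant/resident trait pair."""

    lambda_S_resident: float
    lambda_S_mutant: float
    fitness: float  # per-unit-time growth rate of rare-mutant frequency
    method: str  # {analytic_eq | cycle_average | direct_sim}
    regime: str  # {SC | LC}

    def to_dict(self) -> dict:
        return {
            "lambda_S_resident": self.lambda_S_resident,
            "lambda_S_mutant": self.lambda_S_mutant,
            "fitness": self.fitness,
            "method": self.method,
            "regime": self.regime,
        }


@dataclass
class EvolutionTrace:
    """Trait-substitution sequence of resident ``lambda_S`` values."""

    residents: list[float]
    results: list[InvasionResult]
    regimes: list[str]
    delta: float
    halted: bool = False  # True when a non-positive fitness stopped evolution

    def to_dict(self) -> dict:
        return {
            "residents": list(self.residents),
            "results": [r.to_dict() for r in self.results],
            "regimes": list(self.regimes),
            "delta": self.delta,
            "halted": self.halted,
        }


def classify_regime(params: ModelParams) -> str:
    """``"SC"`` (stable coexistence) or ``"LC"`` (limit cycle).

    Raises when the interior equilibrium does not exist.  A marginal
    equilibrium (on the Hopf line within tolerance) is treated as SC.
    """
    rep = coexistence_equilibrium(params)
    if not rep.exists:
        raise ValueError(
            "no interior coexistence equilibrium at "
            f"lambda_S={params.lambda_S}: regime undefined"
        )
    return "LC" if rep.stability == "unstable" else "SC"


def invasion_fitness_equilibrium(
    lambda_S_mut: float, lambda_S_res: float, params: ModelParams
) -> InvasionResult:
    """Closed-form invasion fitness at the coexistence equilibrium.

    ``S = d (lambda_S_mut - lambda_S_res) / lambda_S_res``: the sign of
    the fitness is the sign of the trait difference, so greater
    exploitation always invades at equilibrium.
    """
    p = params.replace(lambda_S=float(lambda_S_res))
    regime = classify_regime(p)  # raises if the equilibrium does not exist
    S = params.d * (lambda_S_mut - lambda_S_res) / lambda_S_res
    return InvasionResult(lambda_S_res, lambda_S_mut, float(S), "analytic_eq", regime)


def invasion_fitness_cycle(
    lambda_S_mut: float,
    lambda_S_res: float,
    params: ModelParams,
    *,
    resident_cycle: Optional[LimitCycleSummary] = None,
    lc_opts: Optional[dict] = None,
) -> InvasionResult:
    """Cycle-averaged transverse growth rate of a rare mutant.

    Evaluates ``S = (1/T) \\oint R (p_mut - p_bar) dt`` along the
    converged resident cycle by composite Simpson quadrature, where
    ``p_mut = x (1 - P(alone)) lambda_S_mut`` is the mutant payoff in
    the environment (resource and fast fraction) set by the resident.
    """
    p = params.replace(lambda_S=float(lambda_S_res))
    summary = resident_cycle
    if summary is None:
        summary = find_limit_cycle(p, **(lc_opts or {}))
    if not summary.converged or summary.cycle is None:
        raise IntegrationError(
            f"resident cycle at lambda_S={lambda_S_res} did not converge"
        )
    cyc = summary.cycle
    x = np.clip(cyc.x, 0.0, 1.0)
    R = np.clip(cyc.R, 0.0, None)
    bundle = payoffs(x, R, p)
    p_mut = x * (1.0 - probability_alone(R, p)) * lambda_S_mut
    integrand = R * (p_mut - np.asarray(bundle.p_bar))
    S = simpson(integrand, x=cyc.t) / summary.period
    return InvasionResult(lambda_S_res, lambda_S_mut, float(S), "cycle_average", "LC")


def _fit_log_slope(t: np.ndarray, freq: np.ndarray) -> float:
    slope = np.polyfit(t, np.log(freq), 1)[0]
    return float(slope)


def invasion_fitness_direct(
    lambda_S_mut: float,
    lambda_S_res: float,
    params: ModelParams,
    *,
    x0_mut: float = RARE_FREQ,
    n_periods: int = 10,
    sc_window: float = 200.0,
    resident_cycle: Optional[LimitCycleSummary] = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = DEFAULT_METHOD,
    lc_opts: Optional[dict] = None,
) -> InvasionResult:
    """Invasion fitness from direct three-strategy simulation.

    Introduces a mutant at an initial share ``x0_mut`` of the slow
    subpopulation on the resident attractor, integrates the
    five-variable system, and fits the slope of log mutant frequency.
    In the oscillatory regime the frequency is sampled at integer
    multiples of the resident period (so within-cycle oscillation drops
    out of the fit); samples are discarded once the mutant frequency
    exceeds ``RARITY_CEILING`` times its initial value.
    """
    p = params.replace(lambda_S=float(lambda_S_res))
    regime = classify_regime(p)

    if regime == "SC":
        eq = coexistence_equilibrium(p)
        R0, N0, xF0 = eq.location.as_array()
        t_samples = np.linspace(0.0, sc_window, 41)
    else:
        summary = resident_cycle
        if summary is None:
            summary = find_limit_cycle(p, **(lc_opts or {}))
        if not summary.converged or summary.cycle is None:
            raise IntegrationError(
                f"resident cycle at lambda_S={lambda_S_res} did not converge"
            )
        cyc = summary.cycle
        R0, N0, xF0 = cyc.R[0], cyc.N[0], cyc.x[0]
        if n_periods < 3:
            raise ValueError("need at least 3 resident periods for the slope fit")
        t_samples = summary.period * np.arange(n_periods + 1)

    xS0 = 1.0 - xF0
    y0 = np.array([R0, N0, xF0, xS0 * (1.0 - x0_mut), xS0 * x0_mut])

    def f(t: float, y: np.ndarray) -> np.ndarray:
        return rhs_three_strategy(y, p, lambda_S_mut, simplex_tol=1e-3)

    sol = solve_ivp(
        f, (t_samples[0], t_samples[-1]), y0, t_eval=t_samples,
        method=method, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"three-strategy integration failed: {sol.message}")
    drift = np.abs(sol.y[2] + sol.y[3] + sol.y[4] - 1.0).max()
    if drift > 1e-6:
        raise IntegrationError(f"frequency simplex drifted by {drift:.2e}")
    freq = sol.y[4]
    if np.any(freq <= 0):
        raise IntegrationError("mutant frequency hit numerical zero")
    ceiling = x0_mut * xS0 * RARITY_CEILING
    rare = freq <= ceiling
    if rare.sum() < 5:
        rare = np.ones_like(rare, dtype=bool)  # decaying or slow growth: keep all
        if freq[-1] > ceiling:
            raise IntegrationError(
                "mutant left the rare regime too quickly for a stable slope fit"
            )
    S = _fit_log_slope(sol.t[rare], freq[rare])
    return InvasionResult(lambda_S_res, lambda_S_mut, S, "direct_sim", regime)


def trait_substitution(
    params: ModelParams,
    lambda_S_start: float,
    delta: float = 0.1,
    n_steps: int = 50,
    *,
    lc_opts: Optional[dict] = None,
) -> EvolutionTrace:
    """Adaptive-dynamics trait-substitution sequence for ``lambda_S``.

    At each step a mutant with trait ``lambda_S* + delta`` challenges
    the resident; fitness is the closed form in the SC regime and the
    cycle average in the LC regime.  Substitution is deterministic:
    the mutant replaces the resident iff its fitness is positive, and a
    non-positive fitness halts the sequence.  Resident cycles are
    warm-started from the previous resident's cycle.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    opts = dict(lc_opts or {})
    # relaxation onto the cycle is slow just past the Hopf point, and the
    # first post-transition step starts cold; allow long transients there
    opts.setdefault("max_cycles", 5000)
    opts.setdefault("max_time", 100000.0)
    residents = [float(lambda_S_start)]
    results: list[InvasionResult] = []
    regimes: list[str] = []
    halted = False
    warm: Optional[State] = None
    for _ in range(n_steps):
        res = residents[-1]
        p = params.replace(lambda_S=res)
        regime = classify_regime(p)
        if regime == "SC":
            result = invasion_fitness_equilibrium(res + delta, res, params)
            warm = None
        else:
            summary = find_limit_cycle(p, init=warm, **opts)
            if not summary.converged:
                # fresh start before giving up (warm start may sit in a
                # slowly relaxing region)
                summary = find_limit_cycle(p, **opts)
            result = invasion_fitness_cycle(
                res + delta, res, params, resident_cycle=summary
            )
            warm = summary.cycle.final_state() if summary.cycle else None
        results.append(result)
        regimes.append(regime)
        if result.fitness <= 0:
            halted = True
            break
        residents.append(res + delta)
    return EvolutionTrace(residents, results, regimes, delta, halted)


def reciprocal_scaling_check(trace: EvolutionTrace) -> dict:
    """Fit ``log S`` against ``log lambda_S*`` along a substitution trace.

    For the closed-form SC fitness at fixed increment the slope is
    exactly -1 (fitness scales as the reciprocal of the resident
    trait); on cycles the scaling is checked empirically.  Requires at
    least 10 accepted steps.
    """
    accepted = [r for r in trace.results if r.fitness > 0]
    if len(accepted) < 10:
        raise ValueError("need at least 10 accepted steps for the scaling fit")
    logl = np.log([r.lambda_S_resident for r in accepted])
    logS = np.log([r.fitness for r in accepted])
    coeffs, residuals, *_ = np.polyfit(logl, logS, 1, full=True)
    ss_res = float(residuals[0]) if len(residuals) else 0.0
    return {
        "slope": float(coeffs[0]),
        "intercept": float(coeffs[1]),
        "residual_sum_of_squares": ss_res,
        "n_points": len(accepted),
    }
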