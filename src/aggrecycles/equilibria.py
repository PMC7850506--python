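"""Equilibria of the eco-evolutionary model and their linear stability.

Three families of fixed points are handled:

* the interior *coexistence* equilibrium ``(R_hat, N_hat, x_hat)`` where
  fast and slow cells persist at constant frequency;
* boundary equilibria: the consumer-extinction states ``(K, 0, x)`` and
  the fast-only state ``(R_hat, N_hat, 1)``;
* the interior equilibrium of the fixed-composition (neutral)
  two-variable ecological submodel.

Closed-form candidates are derived from the vanishing right-hand side
(payoff equalisation ``p_F = p_S``, demographic balance ``p_bar R = d``
and resource balance ``N = r (1 - R/K)``) and then polished by
multidimensional root finding; the polished root is the source of truth,
the closed forms are accelerators.  Stability is classified from the
eigenvalues of the analytic Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

from .model import ModelParams, State, StateLike, _unpack3, mean_payoff, rhs

__all__ = [
    "EquilibriumReport",
    "MARGINAL_TOL",
    "jacobian",
    "classify_stability",
    "coexistence_candidate",
    "coexistence_equilibrium",
    "boundary_equilibria",
    "existence_condition",
    "neutral_equilibria",
    "neutral_jacobian",
    "neutral_stability_report",
]

#: |leading real part| below which an equilibrium is labelled "marginal"
#: (needed so that bisection brackets behave sanely at a Hopf point)
MARGINAL_TOL = 1e-8


@dataclass(frozen=True)
class EquilibriumReport:
    """Location, spectrum and stability class of one fixed point."""

    label: str  # {extinction | fast_only | coexistence}
    location: State
    eigenvalues: np.ndarray  # complex, sorted by descending real part
    stability: str  # {stable | unstable | marginal}
    leading_real_part: float
    exists: bool
    residual: float = 0.0

    def to_dict(self) -> dict:
        """JSON-friendly representation (eigenvalues as [re, im] pairs)."""
        return {
            "label": self.label,
            "location": {"R": self.location.R, "N": self.location.N, "x": self.location.x},
            "eigenvalues": [[float(ev.real), float(ev.imag)] for ev in self.eigenvalues],
            "stability": self.stability,
            "leading_real_part": float(self.leading_real_part),
            "exists": bool(self.exists),
            "residual": float(self.residual),
        }


def jacobian(state: StateLike, params: ModelParams) -> np.ndarray:
    """Analytic 3x3 Jacobian of the model right-hand side at ``state``.

    The derivative of the solitary probability is ``a/K`` below the clip
    at 1 and zero above it.
    """
    R, N, x = _unpack3(state)
    r, K, d = params.r, params.K, params.d
    lF, lS = params.lambda_F, params.lambda_S
    a = params.aggregation.alone_scale

    pi_raw = a * R / K
    pi = min(max(pi_raw, 0.0), 1.0)
    dpi = a / K if 0.0 <= pi_raw < 1.0 else 0.0

    p_F = pi * lF
    p_S = x * (1.0 - pi) * lS
    p_bar = x * p_F + (1.0 - x) * p_S

    dpF_dR = dpi * lF
    dpS_dR = -x * dpi * lS
    dpS_dx = (1.0 - pi) * lS
    dpbar_dR = x * dpF_dR + (1.0 - x) * dpS_dR
    dpbar_dx = p_F + (1.0 - 2.0 * x) * (1.0 - pi) * lS

    g = p_F - p_S
    J = np.empty((3, 3))
    J[0, 0] = r * (1.0 - 2.0 * R / K) - N
    J[0, 1] = -R
    J[0, 2] = 0.0
    J[1, 0] = N * (dpbar_dR * R + p_bar)
    J[1, 1] = p_bar * R - d
    J[1, 2] = N * R * dpbar_dx
    J[2, 0] = x * (1.0 - x) * (g + R * (dpF_dR - dpS_dR))
    J[2, 1] = 0.0
    J[2, 2] = (1.0 - 2.0 * x) * R * g - x * (1.0 - x) * R * dpS_dx
    return J


def _sorted_eigs(J: np.ndarray) -> np.ndarray:
    eigs = np.linalg.eigvals(J)
    return eigs[np.argsort(-eigs.real)]


def classify_stability(leading_real_part: float, tol: float = MARGINAL_TOL) -> str:
    if abs(leading_real_part) < tol:
        return "marginal"
    return "stable" if leading_real_part < 0 else "unstable"


def _report(label: str, loc: State, params: ModelParams, exists: bool) -> EquilibriumReport:
    eigs = _sorted_eigs(jacobian(loc, params))
    leading = float(eigs[0].real)
    residual = float(np.linalg.norm(rhs(loc, params)))
    return EquilibriumReport(
        label=label,
        location=loc,
        eigenvalues=eigs,
        stability=classify_stability(leading),
        leading_real_part=leading,
        exists=exists,
        residual=residual,
    )


def coexistence_candidate(params: ModelParams) -> State:
    """Closed-form interior fixed-point candidate.

    From payoff equalisation and demographic balance:
    ``R_hat = sqrt(d K / (a lambda_F))``,
    ``x_hat = lambda_F pi_hat / (lambda_S (1 - pi_hat))`` with
    ``pi_hat = a R_hat / K``, and ``N_hat = r (1 - R_hat/K)``.
    The candidate may fall outside the admissible domain (e.g.
    ``x_hat > 1``), in which case the coexistence state does not exist.
    """
    a = params.aggregation.alone_scale
    R_hat = float(np.sqrt(params.d * params.K / (a * params.lambda_F)))
    pi_hat = a * R_hat / params.K
    if pi_hat >= 1.0:
        x_hat = np.inf
    else:
        x_hat = params.lambda_F * pi_hat / (params.lambda_S * (1.0 - pi_hat))
    N_hat = params.r * (1.0 - R_hat / params.K)
    return State(R_hat, N_hat, float(x_hat))


def coexistence_equilibrium(params: ModelParams, *, polish: bool = True) -> EquilibriumReport:
    """Interior coexistence equilibrium with spectrum and stability.

    ``exists`` is set from the direct admissibility check
    ``x_hat in (0, 1)`` and ``0 < R_hat < K``; a report with
    ``exists=False`` (candidate outside the domain) is a valid result,
    not an error.  When the candidate is finite it is polished by a
    Powell-hybrid root find on the full right-hand side.
    """
    cand = coexistence_candidate(params)
    exists = (
        np.isfinite(cand.x)
        and 0.0 < cand.x < 1.0
        and 0.0 < cand.R < params.K
        and cand.N > 0.0
    )
    loc = cand
    if polish and np.isfinite(cand.x):
        sol = optimize.root(
            lambda y: rhs(y, params),
            cand.as_array(),
            jac=lambda y: jacobian(y, params),
            method="hybr",
            tol=1e-13,
        )
        if sol.success and np.linalg.norm(rhs(sol.x, params)) <= np.linalg.norm(
            rhs(cand, params)
        ) + 1e-12:
            loc = State(*sol.x)
    return _report("coexistence", loc, params, exists)


def boundary_equilibria(params: ModelParams) -> list[EquilibriumReport]:
    """Boundary fixed points of the model.

    Returns the consumer-extinction states ``(K, 0, x)`` for the
    representative compositions ``x in {0, 1}`` (the whole ``N = 0``
    manifold is invariant; the replicator direction makes ``x``
    arbitrary there) and, when admissible, the fast-only state
    ``(R_hat, N_hat, 1)`` which shares its ``(R, N)`` coordinates with
    the coexistence point because the mean payoff at ``x = 1`` reduces
    to the fast payoff.
    """
    reports = [
        _report("extinction", State(params.K, 0.0, 0.0), params, True),
        _report("extinction", State(params.K, 0.0, 1.0), params, True),
    ]
    cand = coexistence_candidate(params)
    if 0.0 < cand.R < params.K and cand.N > 0.0:
        reports.append(_report("fast_only", State(cand.R, cand.N, 1.0), params, True))
    return reports


def existence_condition(params: ModelParams) -> dict:
    """Evaluate the two coexistence-existence criteria.

    ``printed_condition`` is the inequality
    ``lambda_F K / d > 1 + lambda_F / lambda_S`` as commonly quoted;
    ``direct_check`` substitutes the closed-form candidate and requires
    ``x_hat in (0, 1)`` and ``R_hat < K``.  The two do not coincide over
    the whole parameter space (the direct condition involves
    ``sqrt(lambda_F K / d)``), so both are reported together with an
    agreement flag rather than silently merged.
    """
    printed = (
        params.lambda_F * params.K / params.d
        > 1.0 + params.lambda_F / params.lambda_S
    )
    direct = coexistence_equilibrium(params, polish=False).exists
    return {
        "printed_condition": bool(printed),
        "direct_check": bool(direct),
        "agree": bool(printed == direct),
    }


# ---------------------------------------------------------------------------
# fixed-composition (neutral) ecological submodel


def neutral_jacobian(R: float, N: float, x_fixed: float, params: ModelParams) -> np.ndarray:
    """Analytic 2x2 Jacobian of the fixed-composition submodel."""
    r, K, d = params.r, params.K, params.d
    lF, lS = params.lambda_F, params.lambda_S
    a = params.aggregation.alone_scale
    pi_raw = a * R / K
    pi = min(max(pi_raw, 0.0), 1.0)
    dpi = a / K if 0.0 <= pi_raw < 1.0 else 0.0
    x = x_fixed
    p_bar = x * pi * lF + (1.0 - x) * x * (1.0 - pi) * lS
    dpbar_dR = dpi * (x * lF - x * (1.0 - x) * lS)
    J = np.empty((2, 2))
    J[0, 0] = r * (1.0 - 2.0 * R / K) - N
    J[0, 1] = -R
    J[1, 0] = N * (dpbar_dR * R + p_bar)
    J[1, 1] = p_bar * R - d
    return J


def neutral_equilibria(params: ModelParams, x_fixed: float) -> list[tuple[float, float]]:
    """Interior equilibria ``(R, N)`` of the fixed-composition submodel.

    Roots of ``p_bar(x_fixed, R) R = d`` are located by a sign-change
    scan over ``(0, K)`` followed by Brent refinement; each root with
    ``N = r (1 - R/K) > 0`` is returned.  The list may be empty.
    """
    if not 0.0 <= x_fixed <= 1.0:
        raise ValueError("x_fixed must lie in [0, 1]")

    def g(R: float) -> float:
        return mean_payoff(x_fixed, R, params) * R - params.d

    grid = np.linspace(1e-12, params.K * (1 - 1e-12), 513)
    vals = np.array([g(R) for R in grid])
    out: list[tuple[float, float]] = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            root = grid[i]
        elif vals[i] * vals[i + 1] < 0:
            root = optimize.brentq(g, grid[i], grid[i + 1], xtol=1e-14, rtol=1e-14)
        else:
            continue
        N = params.r * (1.0 - root / params.K)
        if N > 0:
            out.append((float(root), float(N)))
    return out


def neutral_stability_report(params: ModelParams, x_fixed: float) -> list[dict]:
    """Location, spectrum and stability of each interior neutral equilibrium."""
    reports = []
    for R, N in neutral_equilibria(params, x_fixed):
        eigs = _sorted_eigs(neutral_jacobian(R, N, x_fixed, params))
        leading = float(eigs[0].real)
        reports.append(
            {
                "R": R,
                "N": N,
                "x_fixed": x_fixed,
                "eigenvalues": eigs,
                "leading_real_part": leading,
                "stability": classify_stability(leading),
            }
        )
    return reports
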