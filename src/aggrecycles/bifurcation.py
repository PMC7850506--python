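"""Parameter scans: bifurcation diagrams, Hopf location, 2-D sweeps.

The coexistence equilibrium loses stability through a supercritical
Hopf bifurcation as the exploitation coefficient ``lambda_S`` (or the
solitary-feeding coefficient ``lambda_F``) crosses a critical curve.
This module locates that crossing by root-finding on the leading
eigenvalue real part, assembles 1-D bifurcation diagrams (equilibrium
branch plus limit-cycle extrema), traces the Hopf curve in the
``(lambda_S, lambda_F)`` plane, and builds long-format amplitude /
period / generation-ratio tables over 2-D parameter grids.

All scans warm-start each integration from the neighbouring grid
point's attractor, which keeps transients short and makes runs near the
Hopf curve (where relaxation onto the cycle is slow) tractable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .dynamics import LimitCycleSummary, find_limit_cycle, generation_ratio
from .equilibria import MARGINAL_TOL, coexistence_equilibrium
from .model import ModelParams, State

__all__ = [
    "leading_real_part",
    "hopf_point",
    "hopf_curve",
    "scan_1d",
    "sweep_2d",
    "existence_threshold_lambda_S",
]

logger = logging.getLogger(__name__)

SCANNABLE = ("lambda_S", "lambda_F", "r", "K", "d")


def _with(params: ModelParams, name: str, value: float) -> ModelParams:
    if name not in SCANNABLE:
        raise ValueError(f"unknown scan parameter {name!r}; choose from {SCANNABLE}")
    return params.replace(**{name: float(value)})


def leading_real_part(params: ModelParams, param_name: str, value: float) -> float:
    """Leading eigenvalue real part of the coexistence equilibrium.

    Raises if the interior equilibrium does not exist at this value.
    """
    rep = coexistence_equilibrium(_with(params, param_name, value))
    if not rep.exists:
        raise ValueError(
            f"no interior coexistence equilibrium at {param_name}={value}"
        )
    return rep.leading_real_part


def existence_threshold_lambda_S(params: ModelParams) -> float:
    """Smallest ``lambda_S`` admitting an interior equilibrium.

    From the closed form ``x_hat = lambda_F pi_hat / (lambda_S (1 - pi_hat))``
    the condition ``x_hat < 1`` gives
    ``lambda_S > lambda_F pi_hat / (1 - pi_hat)``.
    """
    a = params.aggregation.alone_scale
    R_hat = math.sqrt(params.d * params.K / (a * params.lambda_F))
    pi_hat = a * R_hat / params.K
    if pi_hat >= 1.0:
        raise ValueError("no interior equilibrium for any lambda_S at these parameters")
    return params.lambda_F * pi_hat / (1.0 - pi_hat)


def hopf_point(
    params: ModelParams,
    param_name: str = "lambda_S",
    bracket: tuple[float, float] = (7.0, 16.0),
    tol: float = 1e-10,
) -> float:
    """Critical parameter value where the equilibrium changes stability.

    Brent root-finding on the leading eigenvalue real part over
    ``bracket`` (a safeguarded bisection); the endpoints must have
    opposite stability.  The leading pair must be genuinely complex at
    the root, otherwise the crossing is not a Hopf point.
    """
    lo, hi = bracket
    f_lo = leading_real_part(params, param_name, lo)
    f_hi = leading_real_part(params, param_name, hi)
    if f_lo * f_hi >= 0:
        raise ValueError(
            f"bracket {bracket} does not straddle a stability change "
            f"(real parts {f_lo:.3g}, {f_hi:.3g})"
        )
    crit = optimize.brentq(
        lambda v: leading_real_part(params, param_name, v), lo, hi,
        xtol=tol, rtol=8 * np.finfo(float).eps,
    )
    rep = coexistence_equilibrium(_with(params, param_name, crit))
    if abs(rep.eigenvalues[0].imag) < 1e-6:
        raise ValueError(
            f"leading eigenvalue real at {param_name}={crit}: not a Hopf point"
        )
    return float(crit)


def hopf_frequency(params: ModelParams, param_name: str, critical: float) -> float:
    """Angular frequency ``|Im(eigenvalue)|`` at the Hopf point."""
    rep = coexistence_equilibrium(_with(params, param_name, critical))
    return float(abs(rep.eigenvalues[0].imag))


def hopf_curve(
    lambda_F_grid: Sequence[float],
    base_params: Optional[ModelParams] = None,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Critical ``lambda_S`` per ``lambda_F``: the Hopf curve.

    For each ``lambda_F`` a bracket is grown upward from just above the
    coexistence-existence threshold (warm-started at the previous
    critical value); grid points where no interior equilibrium or no
    stability change is found are skipped with a log entry.
    """
    params = base_params if base_params is not None else ModelParams()
    rows = []
    prev_crit: Optional[float] = None
    for lF in lambda_F_grid:
        p = params.replace(lambda_F=float(lF))
        try:
            lo = existence_threshold_lambda_S(p) * (1.0 + 1e-6) + 1e-9
        except ValueError as err:
            logger.warning("lambda_F=%g skipped: %s", lF, err)
            continue
        start = max(prev_crit * 0.8, lo) if prev_crit else lo
        crit = _grow_bracket_and_solve(p, start, lo, tol)
        if crit is None:
            logger.warning("lambda_F=%g skipped: no stability change found", lF)
            continue
        prev_crit = crit
        rows.append({"lambda_F": float(lF), "lambda_S_critical": crit})
    return pd.DataFrame(rows, columns=["lambda_F", "lambda_S_critical"])


def _grow_bracket_and_solve(
    params: ModelParams, start: float, lo_bound: float, tol: float,
    factor: float = 1.6, max_value: float = 1e4,
) -> Optional[float]:
    """Walk lambda_S upward until the leading real part changes sign."""
    def f(v: float) -> float:
        return leading_real_part(params, "lambda_S", v)

    lo = max(start, lo_bound)
    try:
        f_lo = f(lo)
    except ValueError:
        return None
    # if we started on the unstable side, walk back down toward the bound
    while f_lo > 0 and lo > lo_bound * (1 + 1e-9):
        lo = max(lo_bound * (1 + 1e-9), lo / factor)
        f_lo = f(lo)
    if f_lo > 0:
        return None
    hi = lo
    f_hi = f_lo
    while f_hi <= 0:
        hi *= factor
        if hi > max_value:
            return None
        f_hi = f(hi)
    return hopf_point(params, "lambda_S", (lo, hi), tol)


_CYCLE_COLS = [
    "R_min", "R_max", "N_min", "N_max", "x_min", "x_max",
    "amplitude_R", "amplitude_N", "amplitude_x", "period",
]


def scan_1d(
    params: ModelParams,
    param_name: str,
    grid: Sequence[float],
    *,
    lc_opts: Optional[dict] = None,
) -> pd.DataFrame:
    """1-D bifurcation diagram along ``grid``.

    Each row carries the interior-equilibrium branch (location,
    stability, leading real part) and, where the equilibrium is
    unstable, the limit-cycle extrema and period.  Simulations are
    warm-started from the previous grid point's attractor.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be sorted ascending")
    opts = dict(lc_opts or {})
    rows = []
    warm: Optional[State] = None
    for v in grid:
        p = _with(params, param_name, v)
        rep = coexistence_equilibrium(p)
        row: dict = {
            param_name: float(v),
            "exists": rep.exists,
            "R_eq": rep.location.R,
            "N_eq": rep.location.N,
            "x_eq": rep.location.x,
            "stability": rep.stability,
            "leading_real_part": rep.leading_real_part,
        }
        row.update({c: math.nan for c in _CYCLE_COLS})
        if rep.exists and rep.stability == "unstable":
            summary = find_limit_cycle(p, init=warm, **opts)
            if summary.converged:
                warm = summary.cycle.final_state()
                row.update(
                    R_min=summary.mins["R"], R_max=summary.maxs["R"],
                    N_min=summary.mins["N"], N_max=summary.maxs["N"],
                    x_min=summary.mins["x"], x_max=summary.maxs["x"],
                    amplitude_R=summary.amplitudes["R"],
                    amplitude_N=summary.amplitudes["N"],
                    amplitude_x=summary.amplitudes["x"],
                    period=summary.period,
                )
            else:
                logger.warning("%s=%g: cycle did not converge", param_name, v)
                warm = None
        else:
            warm = None
        rows.append(row)
    return pd.DataFrame(rows)


def sweep_2d(
    lambda_S_grid: Sequence[float],
    lambda_F_grid: Sequence[float],
    base_params: Optional[ModelParams] = None,
    *,
    lc_opts: Optional[dict] = None,
) -> pd.DataFrame:
    """Long-format amplitude/period/generation-ratio table over a 2-D grid.

    One row per ``(lambda_S, lambda_F)`` cell with columns
    ``amplitude_R, amplitude_N, amplitude_x, period, ratio_max,
    ratio_mean, regime``.  Cells with a stable equilibrium ("SC") carry
    amplitude 0 and an undefined (NaN) period; cells without an interior
    equilibrium are marked "none".  Integrations warm-start along each
    ``lambda_S`` row.
    """
    params = base_params if base_params is not None else ModelParams()
    opts = dict(lc_opts or {})
    rows = []
    for lF in lambda_F_grid:
        warm: Optional[State] = None
        # walk lambda_S downward so cells near the Hopf curve (slow
        # relaxation, small amplitude) inherit a warm start from the
        # well-developed cycles at larger exploitation
        for lS in sorted(np.asarray(lambda_S_grid, dtype=float), reverse=True):
            p = params.replace(lambda_F=float(lF), lambda_S=float(lS))
            rep = coexistence_equilibrium(p)
            row = {
                "lambda_S": float(lS), "lambda_F": float(lF),
                "amplitude_R": math.nan, "amplitude_N": math.nan,
                "amplitude_x": math.nan, "period": math.nan,
                "ratio_max": math.nan, "ratio_mean": math.nan,
            }
            if not rep.exists:
                row["regime"] = "none"
                warm = None
            elif rep.stability != "unstable":
                row["regime"] = "SC"
                row.update(amplitude_R=0.0, amplitude_N=0.0, amplitude_x=0.0)
                warm = None
            else:
                row["regime"] = "LC"
                try:
                    summary = find_limit_cycle(p, init=warm, **opts)
                except Exception as err:  # pragma: no cover - diagnostic path
                    logger.warning("cell (%g, %g) failed: %s", lS, lF, err)
                    summary = None
                if summary is not None and summary.converged:
                    warm = summary.cycle.final_state()
                    ratios = generation_ratio(summary)
                    row.update(
                        amplitude_R=summary.amplitudes["R"],
                        amplitude_N=summary.amplitudes["N"],
                        amplitude_x=summary.amplitudes["x"],
                        period=summary.period,
                        ratio_max=ratios["ratio_vs_max_rate"],
                        ratio_mean=ratios["ratio_vs_mean_rate"],
                    )
                else:
                    logger.warning("cell (%g, %g): cycle did not converge", lS, lF)
                    warm = None
            rows.append(row)
    return (
        pd.DataFrame(rows)
        .sort_values(["lambda_F", "lambda_S"], kind="stable")
        .reset_index(drop=True)
    )
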