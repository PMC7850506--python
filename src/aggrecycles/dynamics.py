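"""Time integration, limit-cycle detection and cycle observables.

The oscillatory regime of the model is an attracting limit cycle around
the unstable coexistence equilibrium: the "life-like" cycle that
alternates a resource-rich, mostly-solitary phase with a
resource-depleted, aggregated phase.  This module integrates the ODEs,
detects convergence onto that cycle with a Poincare section, and
extracts the observables used throughout the analysis: period,
per-variable extrema and amplitudes, cycle averages, solitary/grouped
cell partitions, payoff time series, per-capita birth rates, phase lags
and period-to-generation-time ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .equilibria import EquilibriumReport, coexistence_equilibrium
from .model import ModelParams, State, payoffs, probability_alone, rhs

__all__ = [
    "IntegrationError",
    "Trajectory",
    "LimitCycleSummary",
    "default_initial_state",
    "simulate",
    "derive_observables",
    "find_limit_cycle",
    "generation_ratio",
    "phase_lag",
]

# Tight default tolerances: amplitude/period maps near the Hopf curve
# need local error well below the smallest cycle amplitudes resolved.
DEFAULT_RTOL = 1e-10
DEFAULT_ATOL = 1e-12
DEFAULT_METHOD = "LSODA"

#: allowed excursion outside the admissible domain before an
#: integration is declared invalid
DOMAIN_TOL = 1e-6


class IntegrationError(RuntimeError):
    """Raised when an integration fails or leaves the admissible domain."""


@dataclass
class Trajectory:
    """A time-ordered solution of the model ODEs."""

    t: np.ndarray
    R: np.ndarray
    N: np.ndarray
    x: np.ndarray
    params: ModelParams
    solver_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def states(self) -> np.ndarray:
        """(n, 3) array of ``(R, N, x)`` rows."""
        return np.column_stack([self.R, self.N, self.x])

    def final_state(self) -> State:
        return State(float(self.R[-1]), float(self.N[-1]), float(self.x[-1]))

    def to_dataframe(self) -> pd.DataFrame:
        """Full observable table (see :func:`derive_observables`)."""
        return derive_observables(self)


@dataclass
class LimitCycleSummary:
    """Period, extrema and cycle averages of a detected limit cycle.

    ``converged`` requires successive Poincare return times and cycle
    amplitudes to agree within tolerance; on convergence ``cycle`` holds
    exactly one period of the orbit, sampled from the section crossing.
    Convergence to an equilibrium instead is reported with
    ``converged=False`` and near-zero amplitudes, not as an error.
    """

    params: ModelParams
    converged: bool
    period: float  # nan when no cycle was detected
    mins: dict
    maxs: dict
    amplitudes: dict
    means: dict  # cycle means of R, N, x, p_bar, birth_rate
    n_transient_cycles: int
    cycle: Optional[Trajectory] = None
    equilibrium: Optional[EquilibriumReport] = None

    def to_dict(self) -> dict:
        out = {
            "converged": bool(self.converged),
            "period": None if math.isnan(self.period) else float(self.period),
            "mins": {k: float(v) for k, v in self.mins.items()},
            "maxs": {k: float(v) for k, v in self.maxs.items()},
            "amplitudes": {k: float(v) for k, v in self.amplitudes.items()},
            "means": {k: float(v) for k, v in self.means.items()},
            "n_transient_cycles": int(self.n_transient_cycles),
        }
        return out


def default_initial_state(
    params: ModelParams,
    *,
    rel_perturbation: float = 0.01,
    seed: int = 0,
    equilibrium: Optional[EquilibriumReport] = None,
) -> State:
    """Coexistence equilibrium plus a seeded multiplicative perturbation.

    Each coordinate is multiplied by ``1 + rel_perturbation * u`` with
    ``u`` a fixed unit vector drawn from the seeded generator, giving a
    deterministic, reproducible off-equilibrium start.
    """
    eq = equilibrium if equilibrium is not None else coexistence_equilibrium(params)
    if not eq.exists:
        raise ValueError("no interior coexistence equilibrium to perturb")
    rng = np.random.default_rng(seed)
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    y = eq.location.as_array() * (1.0 + rel_perturbation * u)
    y[2] = min(max(y[2], 1e-12), 1.0 - 1e-12)
    return State(*y).validate()


def _check_domain(y: np.ndarray, params: ModelParams) -> None:
    R, N, x = y
    if (
        np.any(R < -DOMAIN_TOL)
        or np.any(N < -DOMAIN_TOL)
        or np.any(x < -DOMAIN_TOL)
        or np.any(x > 1.0 + DOMAIN_TOL)
    ):
        raise IntegrationError(
            "trajectory left the admissible domain "
            f"(R>=0, N>=0, 0<=x<=1 within {DOMAIN_TOL})"
        )


def simulate(
    params: ModelParams,
    init: State,
    t_span: tuple[float, float],
    *,
    t_eval: Optional[np.ndarray] = None,
    n_points: int = 2001,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = DEFAULT_METHOD,
) -> Trajectory:
    """Integrate the model from ``init`` over ``t_span``.

    Returns a :class:`Trajectory` sampled at ``t_eval`` (default: a
    uniform grid of ``n_points``).  Raises :class:`IntegrationError` if
    the solver fails or the solution leaves the admissible domain beyond
    tolerance.
    """
    init = init if isinstance(init, State) else State(*init)
    init.validate()
    t0, t1 = t_span
    if not t1 > t0:
        raise ValueError("t_span must be increasing")
    if t_eval is None:
        t_eval = np.linspace(t0, t1, n_points)
    sol = solve_ivp(
        lambda t, y: rhs(y, params),
        (t0, t1),
        init.as_array(),
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    _check_domain(sol.y, params)
    meta = {"method": method, "rtol": rtol, "atol": atol}
    return Trajectory(sol.t, sol.y[0], sol.y[1], sol.y[2], params, meta)


def derive_observables(traj: Trajectory) -> pd.DataFrame:
    """Per-time-point observables along a trajectory.

    Columns: ``t, R, N, x, p_F, p_S, p_bar, frac_grouped, n_fast_alone,
    n_fast_grouped, n_slow_alone, n_slow_grouped``.  Group partitions
    follow from random group assembly: the fraction of each type found
    solitary equals the common solitary probability, so the four counts
    always sum to ``N``.  The per-capita birth rate is available as
    ``p_bar * R``.
    """
    params = traj.params
    x = np.clip(traj.x, 0.0, 1.0)
    R = np.clip(traj.R, 0.0, None)
    pi = probability_alone(R, params)
    bundle = payoffs(x, R, params)
    n_fast = traj.N * x
    n_slow = traj.N * (1.0 - x)
    return pd.DataFrame(
        {
            "t": traj.t,
            "R": traj.R,
            "N": traj.N,
            "x": traj.x,
            "p_F": bundle.p_F,
            "p_S": bundle.p_S,
            "p_bar": bundle.p_bar,
            "frac_grouped": 1.0 - pi,
            "n_fast_alone": n_fast * pi,
            "n_fast_grouped": n_fast * (1.0 - pi),
            "n_slow_alone": n_slow * pi,
            "n_slow_grouped": n_slow * (1.0 - pi),
        }
    )


def _cycle_summary_from_samples(
    params: ModelParams,
    cycle: Optional[Trajectory],
    t: np.ndarray,
    R: np.ndarray,
    N: np.ndarray,
    x: np.ndarray,
    period: float,
    converged: bool,
    n_transient: int,
    equilibrium: Optional[EquilibriumReport],
) -> LimitCycleSummary:
    bundle = payoffs(np.clip(x, 0, 1), np.clip(R, 0, None), params)
    birth = np.asarray(bundle.p_bar) * R
    span = t[-1] - t[0]

    def tmean(v: np.ndarray) -> float:
        return float(np.trapezoid(v, t) / span) if span > 0 else float(np.mean(v))

    mins = {"R": float(R.min()), "N": float(N.min()), "x": float(x.min())}
    maxs = {"R": float(R.max()), "N": float(N.max()), "x": float(x.max())}
    amps = {k: maxs[k] - mins[k] for k in mins}
    means = {
        "R": tmean(R),
        "N": tmean(N),
        "x": tmean(x),
        "p_bar": tmean(np.asarray(bundle.p_bar)),
        "birth_rate": tmean(birth),
    }
    return LimitCycleSummary(
        params=params,
        converged=converged,
        period=period,
        mins=mins,
        maxs=maxs,
        amplitudes=amps,
        means=means,
        n_transient_cycles=n_transient,
        cycle=cycle,
        equilibrium=equilibrium,
    )


def find_limit_cycle(
    params: ModelParams,
    init: Optional[State] = None,
    *,
    seed: int = 0,
    rel_perturbation: float = 0.01,
    period_rtol: float = 1e-6,
    amp_rtol: float = 1e-3,
    max_cycles: int = 500,
    chunk_time: float = 100.0,
    max_time: float = 30000.0,
    amp_floor: float = 1e-8,
    n_cycle_samples: int = 2001,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = DEFAULT_METHOD,
) -> LimitCycleSummary:
    """Integrate past transients and characterise the attractor.

    Periodicity is detected on a Poincare section: upward crossings of
    the fast-cell frequency ``x`` through the interior-equilibrium value
    (which the cycle encircles), with peak-to-peak statistics refined
    from dense output between crossings.  Convergence requires the last
    three return times to agree within ``period_rtol`` (relative) and
    the last three per-cycle ``x`` amplitudes within ``amp_rtol``.

    Decay onto a stable equilibrium is reported as ``converged=False``
    with near-zero amplitudes once the per-cycle amplitude falls below
    ``amp_floor`` (or the time/cycle caps are hit).
    """
    eq = coexistence_equilibrium(params)
    if init is None:
        init = default_initial_state(
            params, rel_perturbation=rel_perturbation, seed=seed, equilibrium=eq
        )
    else:
        init = init if isinstance(init, State) else State(*init)
        init.validate()

    if eq.exists:
        x_ref = eq.location.x
        y0 = init.as_array()
        t_now = 0.0
    else:
        # no interior point to encircle: take the running mean of x after
        # a probe integration as the section level
        probe = simulate(params, init, (0.0, chunk_time), n_points=501,
                         rtol=rtol, atol=atol, method=method)
        x_ref = float(np.mean(probe.x[len(probe.x) // 2:]))
        y0 = probe.final_state().as_array()
        t_now = float(probe.t[-1])

    def event(t: float, y: np.ndarray) -> float:
        return y[2] - x_ref

    event.direction = 1.0  # type: ignore[attr-defined]

    f = lambda t, y: rhs(y, params)
    crossings: list[float] = []
    cycle_amps: list[float] = []
    converged = False
    decayed = False
    period = math.nan

    while True:
        sol = solve_ivp(
            f,
            (t_now, t_now + chunk_time),
            y0,
            method=method,
            rtol=rtol,
            atol=atol,
            events=[event],
            dense_output=True,
        )
        if not sol.success:
            raise IntegrationError(f"ODE solver failed: {sol.message}")
        _check_domain(sol.y, params)
        new_cross = [float(tc) for tc in sol.t_events[0]]
        for t_a, t_b in zip(new_cross[:-1], new_cross[1:]):
            ts = np.linspace(t_a, t_b, 201)
            xs = sol.sol(ts)[2]
            cycle_amps.append(float(xs.max() - xs.min()))
        crossings.extend(new_cross)
        y0 = sol.y[:, -1]
        t_now = float(sol.t[-1])

        if len(crossings) >= 4 and len(cycle_amps) >= 3:
            per = np.diff(crossings[-4:])
            amps3 = cycle_amps[-3:]
            ok_p = per.max() - per.min() <= period_rtol * per.mean()
            ok_a = max(amps3) - min(amps3) <= amp_rtol * max(amps3) + 1e-15
            if ok_p and ok_a and max(amps3) > amp_floor:
                converged = True
                period = float(per.mean())
                break
            if amps3[-1] < amp_floor:
                decayed = True
                break
        if len(crossings) > max_cycles or t_now >= max_time:
            break

    n_transient = max(len(crossings) - 4, 0)

    if converged:
        # land exactly on the section, then sample one full period
        land = solve_ivp(
            f, (t_now, t_now + 3 * period), y0, method=method, rtol=rtol,
            atol=atol, events=[event],
        )
        if land.t_events[0].size == 0:
            raise IntegrationError("lost the Poincare section while landing on cycle")
        t_sec = float(land.t_events[0][0])
        y_sec = land.y_events[0][0]
        t_eval = np.linspace(0.0, period, n_cycle_samples)
        one = solve_ivp(
            f, (0.0, period), y_sec, method=method, rtol=rtol, atol=atol,
            t_eval=t_eval,
        )
        if not one.success:
            raise IntegrationError(f"ODE solver failed: {one.message}")
        cycle = Trajectory(
            one.t, one.y[0], one.y[1], one.y[2], params,
            {"method": method, "rtol": rtol, "atol": atol, "section_x": x_ref,
             "section_time": t_sec},
        )
        return _cycle_summary_from_samples(
            params, cycle, one.t, one.y[0], one.y[1], one.y[2], period,
            True, n_transient, eq,
        )

    # no cycle: summarise the tail of the run (decay to equilibrium or
    # non-converged partial data)
    tail = simulate(
        params,
        State(*y0),
        (t_now, t_now + chunk_time),
        n_points=1001,
        rtol=rtol,
        atol=atol,
        method=method,
    )
    est_period = float(np.mean(np.diff(crossings[-4:]))) if len(crossings) >= 4 else math.nan
    if decayed:
        est_period = math.nan
    return _cycle_summary_from_samples(
        params, None, tail.t, tail.R, tail.N, tail.x, est_period,
        False, n_transient, eq,
    )


def generation_ratio(summary: LimitCycleSummary) -> dict:
    """Cycle period expressed in units of the cell generation time.

    The per-capita birth rate ``b(t) = p_bar(t) R(t)`` sets the
    demographic timescale (the net rate ``b - d`` averages to zero over
    a period, so only the birth-like rate yields a meaningful mean).
    Returns ``ratio_vs_max_rate = T * max b`` and
    ``ratio_vs_mean_rate = T * <b>`` together with the per-type birth
    rates ``p_F R`` and ``p_S R`` analogues.
    """
    if not summary.converged or summary.cycle is None:
        raise ValueError("generation ratios require a converged limit cycle")
    cyc = summary.cycle
    bundle = payoffs(np.clip(cyc.x, 0, 1), np.clip(cyc.R, 0, None), cyc.params)
    T = summary.period
    span = cyc.t[-1] - cyc.t[0]

    def stats(rate: np.ndarray) -> tuple[float, float]:
        return float(rate.max()), float(np.trapezoid(rate, cyc.t) / span)

    b_max, b_mean = stats(np.asarray(bundle.p_bar) * cyc.R)
    f_max, f_mean = stats(np.asarray(bundle.p_F) * cyc.R)
    s_max, s_mean = stats(np.asarray(bundle.p_S) * cyc.R)
    return {
        "ratio_vs_max_rate": T * b_max,
        "ratio_vs_mean_rate": T * b_mean,
        "ratio_vs_max_rate_fast": T * f_max,
        "ratio_vs_mean_rate_fast": T * f_mean,
        "ratio_vs_max_rate_slow": T * s_max,
        "ratio_vs_mean_rate_slow": T * s_mean,
        "max_rate": b_max,
        "mean_rate": b_mean,
    }


def _refined_peak_time(t: np.ndarray, v: np.ndarray) -> float:
    """Peak time with parabolic sub-sample refinement (periodic data)."""
    i = int(np.argmax(v))
    n = len(t)
    im, ip = (i - 1) % n, (i + 1) % n
    y0, y1, y2 = v[im], v[i], v[ip]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(t[i])
    delta = 0.5 * (y0 - y2) / denom
    dt = t[1] - t[0]
    return float(t[i] + delta * dt)


def phase_lag(
    cycle: Trajectory,
    series_a: str,
    series_b: str,
    period: Optional[float] = None,
    *,
    min_amplitude: float = 1e-10,
) -> float:
    """Delay of ``series_b``'s peak behind ``series_a``'s peak, in [0, T).

    Operates on one period of a converged cycle (columns of
    :func:`derive_observables`, e.g. ``"R"``, ``"N"``, ``"x"``,
    ``"frac_grouped"``).  Raises for non-oscillatory input.
    """
    df = derive_observables(cycle)
    T = period if period is not None else float(cycle.t[-1] - cycle.t[0])
    a = df[series_a].to_numpy()
    b = df[series_b].to_numpy()
    if np.ptp(a) < min_amplitude or np.ptp(b) < min_amplitude:
        raise ValueError("phase lag undefined for non-oscillatory series")
    t = df["t"].to_numpy()
    lag = (_refined_peak_time(t, b) - _refined_peak_time(t, a)) % T
    return float(lag)
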