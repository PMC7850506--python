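"""Integration, limit-cycle detection and cycle observables."""

import math

import numpy as np
import pytest

from aggrecycles.dynamics import (
    Trajectory,
    default_initial_state,
    derive_observables,
    find_limit_cycle,
    generation_ratio,
    phase_lag,
    simulate,
)
from aggrecycles.equilibria import coexistence_equilibrium
from aggrecycles.model import State


class TestSimulate:
    def test_equilibrium_initial_condition_stays_constant(self, canonical):
        eq = coexistence_equilibrium(canonical)
        traj = simulate(canonical, eq.location, (0.0, 50.0), n_points=501)
        assert np.ptp(traj.R) < 1e-8
        assert np.ptp(traj.N) < 1e-8
        assert np.ptp(traj.x) < 1e-8

    def test_oscillations_are_sustained_at_canonical_params(self, canonical):
        init = default_initial_state(canonical, seed=0)
        traj = simulate(canonical, init, (0.0, 400.0), n_points=8001)
        late = traj.t > 300.0
        for series in (traj.R[late], traj.N[late], traj.x[late]):
            assert np.ptp(series) > 0.1

    def test_low_exploitation_decays_to_equilibrium(self, sc_params):
        eq = coexistence_equilibrium(sc_params)
        init = default_initial_state(sc_params, seed=0)
        traj = simulate(sc_params, init, (0.0, 600.0), n_points=2001)
        final = traj.states[-1]
        assert np.linalg.norm(final - eq.location.as_array()) < 1e-6

    def test_strictly_increasing_times_required(self, canonical):
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 0.0, 1.0]), np.ones(3), np.ones(3),
                       np.full(3, 0.5), canonical)


class TestObservables:
    def test_counts_partition_the_population(self, canonical_cycle):
        df = derive_observables(canonical_cycle.cycle)
        total = (
            df.n_fast_alone + df.n_fast_grouped + df.n_slow_alone + df.n_slow_grouped
        )
        assert np.allclose(total, df.N, rtol=1e-12)

    def test_everyone_solitary_at_carrying_capacity(self, canonical):
        t = np.array([0.0, 1.0])
        traj = Trajectory(t, np.full(2, canonical.K), np.full(2, 2.0),
                          np.full(2, 0.3), canonical)
        df = derive_observables(traj)
        assert np.all(df.frac_grouped == 0.0)
        assert np.all(df.n_fast_grouped == 0.0) and np.all(df.n_slow_grouped == 0.0)

    def test_grouped_fraction_antiphase_with_resource(self, canonical_cycle):
        """Aggregation peaks exactly when the resource bottoms out."""
        cyc = canonical_cycle.cycle
        df = derive_observables(cyc)
        assert np.argmax(df.frac_grouped.to_numpy()) == np.argmin(df.R.to_numpy())
        lag_peak_to_peak = phase_lag(cyc, "R", "frac_grouped", canonical_cycle.period)
        assert 0.0 < lag_peak_to_peak < canonical_cycle.period

    def test_cycle_event_order_matches_boom_bust_narrative(self, canonical_cycle):
        """Within one cycle: resource peak -> x (fast fraction) peak ->
        resource minimum / aggregation maximum -> cheater dominance
        (x minimum) -> resource recovery."""
        cyc = canonical_cycle.cycle
        T = canonical_cycle.period
        t = cyc.t
        t_R_max = t[np.argmax(cyc.R)]
        t_R_min = t[np.argmin(cyc.R)]
        t_x_max = t[np.argmax(cyc.x)]
        t_x_min = t[np.argmin(cyc.x)]
        rel = lambda tt: (tt - t_R_max) % T
        # fast cells bloom while resource is high, aggregate as it
        # depletes, then lose ground to cheaters inside groups
        assert rel(t_x_max) < rel(t_R_min) < rel(t_x_min)


class TestFindLimitCycle:
    def test_canonical_cycle_surrounds_unstable_equilibrium(self, canonical, canonical_cycle):
        s = canonical_cycle
        eq = coexistence_equilibrium(canonical).location
        assert s.converged and s.period > 0
        for var, value in (("R", eq.R), ("N", eq.N), ("x", eq.x)):
            assert s.mins[var] < value < s.maxs[var]

    def test_period_independent_of_initial_condition(self, canonical, canonical_cycle):
        other = find_limit_cycle(canonical, seed=42, rel_perturbation=0.03)
        assert other.converged
        assert other.period == pytest.approx(canonical_cycle.period, rel=1e-4)

    def test_period_and_amplitude_robust_to_tolerance_halving(self, canonical, canonical_cycle):
        tighter = find_limit_cycle(canonical, rtol=5e-11, atol=5e-13)
        assert tighter.period == pytest.approx(canonical_cycle.period, rel=1e-4)
        for var in ("R", "N", "x"):
            assert tighter.amplitudes[var] == pytest.approx(
                canonical_cycle.amplitudes[var], rel=1e-4
            )

    def test_log_population_closes_over_one_period(self, canonical, canonical_cycle):
        """The cycle average of the net per-capita rate p_bar R - d is
        zero: log N returns to itself over a period."""
        assert canonical_cycle.means["birth_rate"] == pytest.approx(
            canonical.d, rel=1e-6
        )

    def test_stable_regime_reports_tiny_amplitude_not_error(self, sc_params):
        s = find_limit_cycle(sc_params)
        assert not s.converged
        assert s.amplitudes["x"] < 1e-6
        assert math.isnan(s.period)


class TestGenerationRatio:
    def test_cycle_outlasts_cell_generation(self, canonical_cycle):
        ratios = generation_ratio(canonical_cycle)
        assert ratios["ratio_vs_max_rate"] > 1.0
        assert ratios["ratio_vs_mean_rate"] > 1.0

    def test_max_rate_ratio_dominates_mean_rate_ratio(self, canonical_cycle):
        ratios = generation_ratio(canonical_cycle)
        assert ratios["ratio_vs_max_rate"] >= ratios["ratio_vs_mean_rate"]

    def test_robust_to_sampling_density(self, canonical, canonical_cycle):
        dense = find_limit_cycle(canonical, n_cycle_samples=4001)
        r1 = generation_ratio(canonical_cycle)
        r2 = generation_ratio(dense)
        assert r2["ratio_vs_max_rate"] == pytest.approx(r1["ratio_vs_max_rate"], rel=0.01)
        assert r2["ratio_vs_mean_rate"] == pytest.approx(r1["ratio_vs_mean_rate"], rel=0.01)

    def test_requires_converged_cycle(self, sc_params):
        s = find_limit_cycle(sc_params)
        with pytest.raises(ValueError):
            generation_ratio(s)


class TestPhaseLag:
    def test_population_lags_resource(self, canonical_cycle):
        lag = phase_lag(canonical_cycle.cycle, "R", "N", canonical_cycle.period)
        assert 0.0 < lag < canonical_cycle.period

    def test_self_lag_is_zero(self, canonical_cycle):
        lag = phase_lag(canonical_cycle.cycle, "R", "R", canonical_cycle.period)
        assert lag == pytest.approx(0.0, abs=1e-9)

    def test_recovers_known_shift_and_matches_cross_correlation(self, canonical_cycle):
        """A circularly shifted copy of a cycle series has a known lag;
        peak matching recovers it and agrees with the circular
        cross-correlation estimate within one output time step."""
        cyc = canonical_cycle.cycle
        T = canonical_cycle.period
        n = len(cyc.t) - 1  # drop duplicated endpoint of the closed orbit
        dt = cyc.t[1] - cyc.t[0]
        shift = 321
        a = cyc.R[:-1]
        b = np.roll(a, shift)  # b(t) = a(t - shift*dt): b lags a
        # peak-based lag straight from the peak times
        t_a = cyc.t[np.argmax(a)]
        t_b = cyc.t[np.argmax(b)]
        lag_peak = (t_b - t_a) % T
        # cross-correlation oracle
        corr = np.fft.irfft(np.conj(np.fft.rfft(a - a.mean())) * np.fft.rfft(b - b.mean()), n)
        lag_xcorr = (np.argmax(corr) / n) * T
        assert lag_peak == pytest.approx(shift * dt, abs=dt + 1e-12)
        assert abs(lag_peak - lag_xcorr) <= dt + 1e-12

    def test_rejects_flat_series(self, canonical, sc_params):
        eq = coexistence_equilibrium(sc_params)
        traj = simulate(sc_params, eq.location, (0.0, 10.0), n_points=101)
        with pytest.raises(ValueError):
            phase_lag(traj, "R", "N")
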