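"""Fixed points, Jacobians, stability classification, existence criteria."""

import numpy as np
import pytest

from aggrecycles.equilibria import (
    boundary_equilibria,
    coexistence_candidate,
    coexistence_equilibrium,
    existence_condition,
    jacobian,
    neutral_stability_report,
)
from aggrecycles.model import ModelParams, State, rhs


def finite_difference_jacobian(state, params, h=1e-6):
    """Central-difference oracle for the analytic Jacobian."""
    y0 = state if isinstance(state, np.ndarray) else state.as_array()
    J = np.empty((3, 3))
    for j in range(3):
        dy = np.zeros(3)
        dy[j] = h
        J[:, j] = (rhs(y0 + dy, params) - rhs(y0 - dy, params)) / (2 * h)
    return J


class TestCoexistenceEquilibrium:
    def test_canonical_location(self, canonical):
        # closed form: R = sqrt(dK/lF), N = r(1 - R/K), x = lF R / (lS (K - R))
        eq = coexistence_equilibrium(canonical)
        assert eq.exists
        assert eq.location.R == pytest.approx(0.1889822365046136, rel=1e-9)
        assert eq.location.N == pytest.approx(0.8110177634953864, rel=1e-9)
        assert eq.location.x == pytest.approx(0.4077825773602246, rel=1e-9)

    def test_residual_below_tolerance_for_random_params(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            params = ModelParams(
                r=rng.uniform(0.5, 2),
                K=rng.uniform(0.5, 2),
                d=rng.uniform(0.5, 2),
                lambda_F=rng.uniform(8, 40),
                lambda_S=rng.uniform(2, 30),
            )
            eq = coexistence_equilibrium(params)
            if eq.exists:
                assert eq.residual <= 1e-10

    def test_unstable_spiral_at_canonical_params(self, canonical):
        eq = coexistence_equilibrium(canonical)
        assert eq.stability == "unstable"
        pair = eq.eigenvalues[:2]
        assert pair[0].real > 0 and abs(pair[0].imag) > 0
        assert pair[0] == pytest.approx(np.conj(pair[1]))

    def test_fast_fraction_vanishes_at_extreme_exploitation(self, canonical):
        eq = coexistence_equilibrium(canonical.replace(lambda_S=1e6), polish=False)
        assert 0 < eq.location.x < 1e-4


class TestJacobian:
    def test_agrees_with_finite_differences(self, canonical):
        rng = np.random.default_rng(11)
        worst = 0.0
        for _ in range(100):
            y = np.array([rng.uniform(0.01, 0.95), rng.uniform(0.05, 2), rng.uniform(0.02, 0.98)])
            J = jacobian(y, canonical)
            worst = max(worst, np.abs(J - finite_difference_jacobian(y, canonical)).max())
        assert worst <= 1e-6

    def test_agrees_with_finite_differences_bounded_rule(self):
        from aggrecycles.model import AggregationRule

        params = ModelParams(aggregation=AggregationRule("bounded", 0.7))
        rng = np.random.default_rng(13)
        for _ in range(20):
            y = np.array([rng.uniform(0.01, 0.95), rng.uniform(0.05, 2), rng.uniform(0.02, 0.98)])
            J = jacobian(y, params)
            assert np.abs(J - finite_difference_jacobian(y, params)).max() <= 1e-6


class TestBoundaryEquilibria:
    def test_all_reported_points_are_fixed(self, canonical):
        for rep in boundary_equilibria(canonical):
            assert rep.residual <= 1e-10

    def test_fast_only_shares_resource_and_population_with_coexistence(self, canonical):
        # at x = 1 the mean payoff reduces to p_F, so the (R, N)
        # subsystem equilibrium coincides with the interior one
        coex = coexistence_equilibrium(canonical)
        fast = [r for r in boundary_equilibria(canonical) if r.label == "fast_only"]
        assert len(fast) == 1
        assert fast[0].location.R == pytest.approx(coex.location.R, rel=1e-10)
        assert fast[0].location.N == pytest.approx(coex.location.N, rel=1e-10)
        assert fast[0].location.x == 1.0

    def test_extinction_unstable_when_fast_growth_beats_death(self, canonical):
        # lambda_F K > d: an all-fast population invades the empty state
        ext = [
            r for r in boundary_equilibria(canonical)
            if r.label == "extinction" and r.location.x == 1.0
        ]
        assert ext[0].stability == "unstable"


class TestExistenceCondition:
    def test_canonical_params_satisfy_both_criteria(self, canonical):
        res = existence_condition(canonical)
        assert res == {"printed_condition": True, "direct_check": True, "agree": True}

    def test_boundary_equality_is_not_existence(self):
        # lF K / d == 1 + lF / lS exactly: the strict inequality fails
        lF = 28.0
        lS = lF / (lF - 1.0)
        res = existence_condition(ModelParams(lambda_F=lF, lambda_S=lS))
        assert res["printed_condition"] is False

    def test_disagreement_region_is_reported_not_hidden(self, canonical):
        """The quoted inequality and direct substitution disagree for
        intermediate exploitation; the report flags this."""
        res = existence_condition(canonical.replace(lambda_S=4.0))
        assert res["printed_condition"] is True
        assert res["direct_check"] is False
        assert res["agree"] is False
        # direct check is the ground truth: x_hat falls outside (0, 1)
        cand = coexistence_candidate(canonical.replace(lambda_S=4.0))
        assert cand.x > 1.0

    def test_agreement_flag_recorded_across_random_sweep(self):
        rng = np.random.default_rng(3)
        flags = []
        for _ in range(50):
            params = ModelParams(
                lambda_F=rng.uniform(8, 40), lambda_S=rng.uniform(2, 30)
            )
            res = existence_condition(params)
            direct = coexistence_equilibrium(params, polish=False).exists
            assert res["direct_check"] == direct
            flags.append(res["agree"])
        assert any(flags)  # the criteria do coincide over part of the space


class TestStabilityAlongPath:
    def test_labels_flip_exactly_at_sign_change(self, canonical):
        """Stability labels are consistent with the leading real part
        everywhere along a 1-parameter path through the Hopf point."""
        grid = np.linspace(8.0, 20.0, 49)
        labels, leads = [], []
        for lS in grid:
            rep = coexistence_equilibrium(canonical.replace(lambda_S=lS))
            labels.append(rep.stability)
            leads.append(rep.leading_real_part)
        for lab, lead in zip(labels, leads):
            expected = "stable" if lead < -1e-8 else ("unstable" if lead > 1e-8 else "marginal")
            assert lab == expected
        flips = sum(1 for a, b in zip(labels, labels[1:]) if a != b)
        assert flips == 1


class TestNeutralModelStability:
    def test_interior_equilibria_stable_for_random_draws(self):
        """The purely ecological submodel never oscillates: every
        interior equilibrium found over random parameters is stable."""
        rng = np.random.default_rng(19)
        found = 0
        while found < 40:
            params = ModelParams(
                r=rng.uniform(0.5, 2),
                K=rng.uniform(0.5, 2),
                d=rng.uniform(0.5, 2),
                lambda_F=rng.uniform(8, 40),
                lambda_S=rng.uniform(2, 30),
            )
            reports = neutral_stability_report(params, rng.uniform(0.05, 0.95))
            for rep in reports:
                assert rep["leading_real_part"] < 0
                found += 1
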