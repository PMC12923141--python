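"""Unit and property tests for the payoff, gradient, feedback, and Jacobian core."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, strategies as st

import coevrisk as cr
from coevrisk import DomainError, ModelParams, State


def mk(N=8, M=5, b=2.0, **kw):
    base = dict(
        N=N, M=M, b=b, alpha=0.3, beta=0.1, mu1=0.25, mu2=0.3,
        theta1=0.5, theta2=0.5, theta3=0.6, theta4=0.6,
    )
    base.update(kw)
    return ModelParams(**base)


class TestParamsAndState:
    @pytest.mark.parametrize(
        "bad",
        [
            dict(N=1),
            dict(M=0),
            dict(M=9),
            dict(b=0.0),
            dict(alpha=0.05),  # alpha <= beta
            dict(beta=-0.1),
            dict(mu1=0.0),
            dict(theta3=-1.0),
            dict(eps1=0.0),
        ],
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(DomainError):
            mk(**bad)

    def test_state_box_validation(self):
        p = mk()
        State(0.5, 0.5, 0.2).validate(p)
        with pytest.raises(DomainError):
            State(1.2, 0.5, 0.2).validate(p)
        with pytest.raises(DomainError):
            State(0.5, 0.5, 0.05).validate(p)  # below beta

    def test_replace_revalidates(self):
        p = mk()
        assert p.replace(M=3).M == 3
        with pytest.raises(DomainError):
            p.replace(M=20)


class TestPayoffs:
    def test_threshold_met_at_equality(self):
        # chi(0) = 1: exactly M cooperators already secures the endowment
        p = mk()
        assert cr.payoff_cooperator(p.M, p, r=0.7, c=0.25) == pytest.approx(p.b - 0.25)
        assert cr.payoff_defector(p.M, p, r=0.7) == pytest.approx(p.b)

    def test_failed_group_at_maximal_risk(self):
        p = mk()
        assert cr.payoff_cooperator(p.M - 1, p, r=1.0, c=0.25) == pytest.approx(-0.25)
        assert cr.payoff_defector(p.M - 1, p, r=1.0) == 0.0
        assert cr.payoff_defector(p.M - 1, p, r=0.0) == pytest.approx(p.b)

    def test_partial_risk_value(self):
        # direct evaluation: b*(1-r) - c = 2*0.5 - 0.3
        p = mk()
        assert cr.payoff_cooperator(3, p, r=0.5, c=0.3) == pytest.approx(0.7)

    def test_domain_errors(self):
        p = mk()
        with pytest.raises(DomainError):
            cr.payoff_cooperator(-1, p, r=0.5, c=0.2)
        with pytest.raises(DomainError):
            cr.payoff_defector(3, p, r=1.5)


class TestGradient:
    def test_no_risk_reduces_to_cost(self):
        p = mk()
        for x in (0.0, 0.3, 1.0):
            assert cr.gradient_summation(x, 0.0, 0.22, p) == pytest.approx(-0.22)

    def test_closed_form_half(self):
        # b * C(7,4) * 0.5^7 = 2 * 35 / 128
        p = mk()
        assert cr.gradient_closed_form(0.5, 1.0, 0.0, p) == pytest.approx(70 / 128)
        assert cr.gradient_summation(0.5, 1.0, 0.0, p) == pytest.approx(70 / 128)

    def test_boundary_gradient_is_minus_cost(self):
        p = mk()
        assert cr.gradient_closed_form(0.0, 0.8, 0.2, p) == pytest.approx(-0.2)
        assert cr.gradient_closed_form(1.0, 0.8, 0.2, p) == pytest.approx(-0.2)

    def test_summation_equals_closed_form_over_random_draws(self, rng):
        # binomial-identity collapse of the group-sampled expectation
        for _ in range(1000):
            N = int(rng.integers(2, 13))
            M = int(rng.integers(1, N + 1))
            p = mk(N=N, M=M, b=float(rng.uniform(0.5, 5.0)))
            x, r = rng.uniform(0, 1, 2)
            c = rng.uniform(p.beta, p.alpha)
            assert abs(
                cr.gradient_summation(x, r, c, p) - cr.gradient_closed_form(x, r, c, p)
            ) <= 1e-10

    @given(x=st.floats(0, 1), r=st.floats(0, 1), m=st.integers(1, 8))
    def test_summation_equals_closed_form_property(self, x, r, m):
        p = mk(M=m)
        assert cr.gradient_summation(x, r, 0.2, p) == pytest.approx(
            cr.gradient_closed_form(x, r, 0.2, p), abs=1e-10
        )

    def test_benefit_peak_location_and_value(self):
        # unique interior maximum at (M-1)/(N-1), closed-form peak value
        p = mk()
        x_hat, peak = cr.benefit_peak(p)
        assert x_hat == pytest.approx(4 / 7)
        expected = 2 * comb(7, 4) * (4 / 7) ** 4 * (3 / 7) ** 3
        assert peak == pytest.approx(expected, rel=1e-12)
        xs = np.linspace(0, 1, 2001)
        vals = [cr.benefit(x, p) for x in xs]
        assert max(vals) <= peak + 1e-12


class TestFeedbacks:
    def test_risk_feedback_faces_and_balance(self):
        p = mk()
        assert cr.risk_feedback(0.4, 0.0, p) == 0.0
        assert cr.risk_feedback(0.4, 1.0, p) == 0.0
        x_bal = p.mu1 / (p.mu1 + p.mu2)
        assert cr.risk_feedback(x_bal, 0.37, p) == pytest.approx(0.0, abs=1e-15)
        # all defectors at half risk: 0.25 * mu1
        assert cr.risk_feedback(0.0, 0.5, p) == pytest.approx(0.0625)

    def test_cost_feedback_faces_and_signs(self):
        p = mk()
        assert cr.cost_feedback(0.5, 0.5, p.alpha, p) == 0.0
        assert cr.cost_feedback(0.5, 0.5, p.beta, p) == 0.0
        # full defection at maximal risk drives the cost up
        assert cr.cost_feedback(0.0, 1.0, 0.2, p) > 0.0

    def test_cost_feedback_value(self):
        p = mk(mu1=0.7, theta3=0.2)
        val = cr.cost_feedback(0.7, 0.2204, 0.2, p)
        drive = 0.5 * 0.3 - 0.5 * 0.7 + 0.2 * 0.2204 - 0.6 * (1 - 0.2204)
        assert val == pytest.approx(0.01 * drive, rel=1e-12)

    def test_risk_feedback_decreasing_in_x(self, rng):
        p = mk()
        for _ in range(20):
            r = rng.uniform(0.05, 0.95)
            xs = np.sort(rng.uniform(0, 1, 5))
            vals = [cr.risk_feedback(x, r, p) for x in xs]
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_cost_feedback_monotone_in_r_and_x(self, rng):
        p = mk()
        c = 0.2
        assert cr.cost_feedback(0.3, 0.9, c, p) > cr.cost_feedback(0.3, 0.1, c, p)
        assert cr.cost_feedback(0.1, 0.5, c, p) > cr.cost_feedback(0.9, 0.5, c, p)


class TestVectorField:
    def test_corners_are_fixed_points(self):
        p = mk()
        for x in (0, 1):
            for r in (0, 1):
                for c in (p.alpha, p.beta):
                    assert np.linalg.norm(cr.vector_field((x, r, c), p)) == 0.0

    def test_boundary_components_vanish(self, rng):
        p = mk()
        for _ in range(20):
            s = rng.uniform(0, 1, 3)
            c = p.beta + s[2] * (p.alpha - p.beta)
            assert cr.vector_field((0.0, s[1], c), p)[0] == 0.0
            assert cr.vector_field((1.0, s[1], c), p)[0] == 0.0
            assert cr.vector_field((s[0], 0.0, c), p)[1] == 0.0
            assert cr.vector_field((s[0], 1.0, c), p)[1] == 0.0
            assert cr.vector_field((s[0], s[1], p.alpha), p)[2] == 0.0
            assert cr.vector_field((s[0], s[1], p.beta), p)[2] == 0.0

    def test_timescale_scaling(self):
        # doubling eps1 halves dx/dt only; doubling eps2 halves dr/dt only
        p = mk()
        s = (0.4, 0.6, 0.2)
        v = cr.vector_field(s, p)
        v1 = cr.vector_field(s, p.replace(eps1=2.0))
        v2 = cr.vector_field(s, p.replace(eps2=2.0))
        assert v1[0] == pytest.approx(v[0] / 2) and v1[1] == v[1] and v1[2] == v[2]
        assert v2[1] == pytest.approx(v[1] / 2) and v2[0] == v[0] and v2[2] == v[2]

    def test_pluggable_feedbacks(self):
        p = mk()
        v = cr.vector_field((0.4, 0.6, 0.2), p, feedbacks=(
            lambda x, r, q: 0.0, lambda x, r, c, q: 0.0))
        assert v[1] == 0.0 and v[2] == 0.0 and v[0] != 0.0


class TestJacobian:
    def test_matches_finite_differences(self, random_params, rng):
        h = 1e-6
        for p in random_params[:100]:
            x = rng.uniform(0.05, 0.95)
            r = rng.uniform(0.05, 0.95)
            c = p.beta + rng.uniform(0.05, 0.95) * (p.alpha - p.beta)
            s = np.array([x, r, c])
            jac = cr.jacobian(s, p)
            fd = np.zeros((3, 3))
            for j in range(3):
                e = np.zeros(3)
                e[j] = h
                fd[:, j] = (cr.vector_field(s + e, p) - cr.vector_field(s - e, p)) / (2 * h)
            assert np.max(np.abs(jac - fd)) < 1e-6

    def test_no_cost_to_risk_coupling(self, rng):
        p = mk()
        for _ in range(10):
            s = [rng.uniform(0, 1), rng.uniform(0, 1), rng.uniform(p.beta, p.alpha)]
            assert cr.jacobian(s, p)[1, 2] == 0.0

    def test_tragedy_corner_strategy_eigenvalue(self):
        # at (0, 1, alpha) the strategy direction decays at rate -alpha
        p = mk()
        jac = cr.jacobian((0.0, 1.0, p.alpha), p)
        assert jac[0, 0] == pytest.approx(-p.alpha)
        assert np.all(np.linalg.eigvals(jac).real < 0)


class TestSuccessRate:
    def test_exact_half_probability(self):
        # rational-arithmetic oracle: P(X >= 5), X ~ Bin(8, 1/2) = 93/256
        p = mk()
        oracle = 1 - sum(
            Fraction(comb(8, k)) * Fraction(1, 2) ** 8 for k in range(5)
        )
        assert oracle == Fraction(93, 256)
        assert cr.success_rate(0.5, p) == float(Fraction(93, 256))

    def test_boundaries(self):
        p = mk()
        assert cr.success_rate(0.0, p) == 0.0
        assert cr.success_rate(1.0, p) == 1.0
        with pytest.raises(DomainError):
            cr.success_rate(1.5, p)

    def test_matches_scipy_binomial_tail(self, rng):
        from scipy.stats import binom

        for _ in range(50):
            N = int(rng.integers(2, 15))
            M = int(rng.integers(1, N + 1))
            q = float(rng.uniform(0, 1))
            p = mk(N=N, M=M)
            assert cr.success_rate(q, p) == pytest.approx(
                float(binom.sf(M - 1, N, q)), abs=1e-12
            )

    def test_monotone_in_p_and_M(self):
        p = mk()
        qs = np.linspace(0, 1, 21)
        vals = [cr.success_rate(q, p) for q in qs]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))
        by_m = [cr.success_rate(0.6, mk(M=m)) for m in range(1, 9)]
        assert all(a >= b - 1e-12 for a, b in zip(by_m, by_m[1:]))
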