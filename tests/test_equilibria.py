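"""Closed-form equilibria versus independent oracles; case logic."""

import math

import numpy as np
import pytest

from hive_allee import (
    Case,
    SocialParams,
    Stability,
    classify_case,
    discriminant_quantity,
    net_rate,
    quadratic_coefficients,
    solve_equilibria,
    stability,
)

from conftest import oracle_positive_roots, random_param_sets


class TestQuadraticCoefficients:
    def test_default_fixture_values(self, case2):
        q = quadratic_coefficients(case2)
        assert q.a == pytest.approx(-0.02)
        assert q.b == pytest.approx(980.0)
        assert q.c == pytest.approx(-1_200_000.0)

    def test_forced_zero_b(self, case2):
        p = case2.replace(lam=case2.alpha * case2.beta
                          + case2.mu * case2.theta + case2.mu * case2.beta)
        assert quadratic_coefficients(p).b == pytest.approx(0.0, abs=1e-9)

    def test_forced_zero_c(self, case2):
        p = case2.replace(lam=case2.theta * (case2.alpha + case2.mu))
        assert quadratic_coefficients(p).c == pytest.approx(0.0, abs=1e-6)

    def test_a_is_always_negative_mu(self):
        for p in random_param_sets(20, seed=7):
            assert quadratic_coefficients(p).a == -p.mu


class TestDiscriminantQuantity:
    def test_default_fixture_value(self, case2):
        # b^2 / (4*mu*beta*(mu*theta + alpha*theta - lam))
        assert discriminant_quantity(case2) == pytest.approx(
            980.0**2 / (4 * 0.02 * 5000 * 240), rel=1e-12
        )

    def test_nan_on_zero_denominator(self):
        # dyadic values make theta*(alpha+mu) - lam exactly zero in floats
        p = SocialParams(lam=2250.0, theta=16000.0, alpha=0.125, beta=5000.0,
                         mu=0.015625)
        assert p.mu * p.theta + p.alpha * p.theta - p.lam == 0.0
        assert math.isnan(discriminant_quantity(p))
        from hive_allee import solve_equilibria as se
        assert se(p).boundary_c_zero

    def test_equals_one_exactly_at_vanishing_discriminant(self, case2):
        # independent fold location: zeros of disc(mu), itself quadratic in mu
        mus = np.linspace(0.02, 0.2, 2001)
        disc = [quadratic_coefficients(case2.replace(mu=m)).discriminant for m in mus]
        coef = np.polyfit(mus, disc, 2)
        mu_star = min(np.roots(coef))
        assert discriminant_quantity(case2.replace(mu=float(mu_star))) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_sign_agrees_with_discriminant(self):
        checked = 0
        for p in random_param_sets(200, seed=11):
            denom = p.mu * p.theta + p.alpha * p.theta - p.lam
            if denom <= 0:
                continue
            dq = discriminant_quantity(p)
            disc = quadratic_coefficients(p).discriminant
            assert np.sign(dq - 1.0) == np.sign(disc)
            checked += 1
        assert checked > 20

    @pytest.mark.parametrize("name,lo,hi,direction", [
        ("lam", 1100.0, 2200.0, +1),
        ("theta", 14500.0, 60000.0, -1),
        ("alpha", 0.11, 0.30, -1),
        ("beta", 5000.0, 11500.0, -1),
        ("mu", 0.006, 0.06, -1),
    ])
    def test_monotone_in_each_parameter(self, case2, name, lo, hi, direction):
        """The collapse index rises with recruitment capacity and falls
        with every mortality or cooperation-cost parameter."""
        vals = np.linspace(lo, hi, 50)
        dq = np.array([discriminant_quantity(case2.replace(**{name: float(v)}))
                       for v in vals])
        assert np.all(np.isfinite(dq))
        assert np.all(direction * np.diff(dq) > 0)


class TestSolveEquilibria:
    def test_default_fixture_roots(self, case2):
        rep = solve_equilibria(case2)
        assert rep.n_crit == pytest.approx(1256.7214, rel=1e-6)
        assert rep.n_stable == pytest.approx(47743.2786, rel=1e-6)
        assert rep.case is Case.CASE_2

    def test_zero_always_an_equilibrium(self, fx):
        for p in fx.values():
            rep = solve_equilibria(p)
            assert rep.zero_equilibrium.value == 0.0

    def test_roots_are_equilibria_of_the_rate_function(self, fx):
        for p in fx.values():
            for r in solve_equilibria(p).positive_roots:
                assert abs(net_rate(r, p)) <= 1e-8 * p.lam

    def test_case1_has_exactly_one_positive_root(self, fx):
        rep = solve_equilibria(fx["case1"])
        assert rep.case is Case.CASE_1
        assert len(rep.positive_roots) == 1
        assert rep.n_crit is None

    def test_case3_has_no_positive_roots(self, fx):
        p = fx["case3"]
        rep = solve_equilibria(p)
        assert rep.positive_roots == []
        n = np.linspace(1.0, 1e6, 5000)
        assert np.all(net_rate(n, p) < 0)

    def test_matches_bracketing_oracle_on_random_sets(self):
        for p in random_param_sets(60, seed=13):
            closed = solve_equilibria(p).positive_roots
            expected = oracle_positive_roots(p)
            assert len(closed) == len(expected)
            for got, ref in zip(closed, expected):
                assert got == pytest.approx(ref, rel=1e-6)

    def test_ordering_when_two_roots(self):
        for p in random_param_sets(60, seed=13):
            rep = solve_equilibria(p)
            if rep.n_crit is not None and rep.n_stable is not None:
                assert rep.n_crit < rep.n_stable


class TestClassification:
    def test_intercept_rules(self, case2):
        assert classify_case(case2.replace(theta=8000.0)) is Case.CASE_1
        assert classify_case(case2) is Case.CASE_2
        # lam/theta below mu: everywhere-dominant mortality
        assert classify_case(case2.replace(mu=0.2)) is Case.CASE_3

    def test_case2_iff_two_distinct_positive_roots(self):
        for p in random_param_sets(200, seed=17):
            rep = solve_equilibria(p)
            two = rep.n_crit is not None and rep.n_stable is not None
            assert (rep.case is Case.CASE_2) == two

    def test_two_roots_imply_recruitment_intercept_below_mortality(self):
        for p in random_param_sets(200, seed=19):
            if len(solve_equilibria(p).positive_roots) == 2:
                assert p.lam / p.theta < p.alpha + p.mu


class TestStability:
    def test_case2_stability_pattern(self, case2):
        rep = solve_equilibria(case2)
        labels = {round(e.value): e.stability for e in rep.equilibria}
        assert labels[0] is Stability.STABLE
        assert labels[round(rep.n_crit)] is Stability.UNSTABLE
        assert labels[round(rep.n_stable)] is Stability.STABLE

    def test_sign_matches_central_difference_slope(self, case2):
        rep = solve_equilibria(case2)
        for r in rep.positive_roots:
            h = 1e-3 * r
            slope = (net_rate(r + h, case2) - net_rate(r - h, case2)) / (2 * h)
            expected = Stability.STABLE if slope < 0 else Stability.UNSTABLE
            assert stability(r, case2) is expected

    def test_non_equilibrium_rejected(self, case2):
        with pytest.raises(ValueError, match="not an equilibrium"):
            stability(12345.0, case2)

    def test_degenerate_at_exact_fold(self, case2):
        # construct a repeated root by solving disc(mu)=0 to machine precision
        from scipy.optimize import brentq
        mu_star = brentq(
            lambda m: quadratic_coefficients(case2.replace(mu=m)).discriminant,
            0.02, 0.2, xtol=1e-16, rtol=8.9e-16,
        )
        rep = solve_equilibria(case2.replace(mu=mu_star))
        if rep.discriminant == 0.0:  # exact hit, else the fold is between floats
            assert any(e.stability is Stability.DEGENERATE for e in rep.equilibria)
        else:
            assert abs(rep.discriminant) < 1e-4 * quadratic_coefficients(case2).b ** 2


class TestRootMergeContinuity:
    def test_branches_converge_to_repeated_root_at_fold(self, case2):
        from scipy.optimize import brentq
        mu_star = brentq(
            lambda m: quadratic_coefficients(case2.replace(mu=m)).discriminant,
            0.02, 0.2, rtol=8.9e-16,
        )
        gaps = []
        for eps in (1e-2, 1e-4, 1e-6):
            p = case2.replace(mu=mu_star * (1 - eps))
            rep = solve_equilibria(p)
            assert rep.n_crit is not None
            q = rep.coefficients
            merged = -q.b / (2 * q.a)
            gaps.append(rep.n_stable - rep.n_crit)
            assert rep.n_crit == pytest.approx(merged, rel=20 * math.sqrt(eps))
            assert rep.n_stable == pytest.approx(merged, rel=20 * math.sqrt(eps))
        assert gaps[0] > gaps[1] > gaps[2] > 0
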