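"""Closed-form leading-order solutions and their certification."""

import numpy as np
import pytest

from tissuetarget import (
    DimensionlessParameters,
    ExpansionValidityWarning,
    central_A0,
    cosh_ratio,
    leading_order_A,
    leading_order_B,
    leading_order_C,
    leading_order_profile,
    small_lambda1_profile,
)

from conftest import leading_order_oracle, random_o1_params


def P(l1=0, l2=0, l3=0, l4=0, l5=0, muA=1, muB=1, dA=1, dB=1):
    return DimensionlessParameters(l1, l2, l3, l4, l5, muA, muB, dA, dB)


# Frozen extended-precision values (mpmath, 40 digits).
INV_COSH_1 = 0.6480542736638853995749773532261503231084  # 1/cosh(1)
INV_COSH_SQRT50 = 0.001698650184109975114610121394554837096  # 1/cosh(sqrt(50))


class TestCoshRatio:
    @pytest.mark.parametrize("k", [0.0, 1.0, 50.0, 710.0, 1e6, 1e12])
    def test_equals_one_at_boundary(self, k):
        assert cosh_ratio(k, 1.0) == pytest.approx(1.0, rel=1e-14)

    def test_identity_for_zero_wavenumber(self):
        assert cosh_ratio(0.0, 0.3) == 1.0

    def test_frozen_value(self):
        assert cosh_ratio(1.0, 0.0) == pytest.approx(INV_COSH_1, rel=1e-13)

    def test_matches_extended_precision(self):
        """>= 12 significant digits against mpmath across stiff wavenumbers."""
        import mpmath

        mpmath.mp.dps = 40
        for k in (0.5, 3.0, 30.0, 300.0, 3000.0):
            for x in (0.0, 0.25, 0.9, 0.999, 1.0):
                expected = float(mpmath.cosh(k * x) / mpmath.cosh(k))
                if expected == 0.0:
                    continue  # beyond double-precision underflow
                assert cosh_ratio(k, x) == pytest.approx(expected, rel=1e-12)

    def test_no_overflow_for_huge_wavenumber(self):
        vals = cosh_ratio(1e6, np.linspace(0, 1, 11))
        assert np.all(np.isfinite(vals))
        assert vals[-1] == pytest.approx(1.0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            cosh_ratio(1.0, 1.5)
        with pytest.raises(ValueError):
            cosh_ratio(1.0, -0.1)


class TestLeadingOrderC:
    def test_uniform_without_breakdown(self):
        assert np.all(leading_order_C(np.linspace(0, 1, 7), P()) == 1.0)

    def test_boundary_value(self):
        for l2 in (0.5, 50.0, 1e8):
            assert leading_order_C(1.0, P(l2=l2)) == pytest.approx(1.0)

    def test_frozen_centre_value(self):
        assert leading_order_C(0.0, P(l2=50)) == pytest.approx(
            INV_COSH_SQRT50, rel=1e-12
        )

    def test_strictly_increasing_for_positive_breakdown(self):
        x = np.linspace(0, 1, 500)
        for l2 in (0.3, 5.0, 400.0):
            c = leading_order_C(x, P(l2=l2))
            assert np.all(np.diff(c) > 0)


class TestLeadingOrderA:
    def test_uniform_without_reactions(self):
        x = np.linspace(0, 1, 11)
        A0, B0, C0 = leading_order_profile(x, P())
        assert np.all(A0 == 1.0) and np.all(B0 == 1.0) and np.all(C0 == 1.0)

    def test_saturation_at_fast_breakdown(self):
        """With no removal, A0(0) approaches 1 + mu_A/delta_A = 2."""
        assert leading_order_A(0.0, P(l2=1e8)) == pytest.approx(2.0, abs=1e-3)

    def test_matches_independent_bvp(self):
        x = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        p = P(l2=50, l3=0.5)
        Ao, _, _ = leading_order_oracle(p, x)
        np.testing.assert_allclose(leading_order_A(x, p), Ao, atol=1e-8)

    def test_degenerate_branch_matches_bvp(self):
        p = P(l2=2.0, l3=2.0)  # delta_A*lambda2 == lambda3 resonance
        x = np.linspace(0, 1, 9)
        Ao, _, _ = leading_order_oracle(p, x)
        np.testing.assert_allclose(leading_order_A(x, p), Ao, atol=1e-8)

    def test_branch_continuity(self):
        """Regular branch just off the resonance locus agrees with the
        degenerate branch uniformly on [0, 1]."""
        x = np.linspace(0, 1, 201)
        for l2 in (0.5, 2.0, 10.0):
            on = leading_order_A(x, P(l2=l2, l3=l2))
            for sign in (+1, -1):
                off = leading_order_A(x, P(l2=l2, l3=l2 * (1 + sign * 1e-6)))
                assert np.max(np.abs(on - off)) < 1e-4


class TestLeadingOrderB:
    def test_uniform_without_removal_or_source(self):
        assert np.all(leading_order_B(np.linspace(0, 1, 7), P(l2=3)) == 1.0)

    def test_pure_removal_depletes_centre(self):
        p = P(l2=3, l4=2.0, l5=0.0)
        x = np.linspace(0, 1, 101)
        b = leading_order_B(x, p)
        np.testing.assert_allclose(b, cosh_ratio(np.sqrt(2.0), x), rtol=1e-12)
        assert np.argmin(b) == 0

    def test_matches_independent_bvp(self):
        x = np.array([0.0, 0.3, 0.7, 1.0])
        p = P(l2=5, l4=0.2, l5=1.0)
        _, Bo, _ = leading_order_oracle(p, x)
        np.testing.assert_allclose(leading_order_B(x, p), Bo, atol=1e-8)

    def test_parabolic_limit(self):
        """Uniform undepleted complex with a source: B0 is a parabola."""
        p = P(l2=0.0, l4=0.0, l5=1.4, dB=0.7)
        x = np.linspace(0, 1, 11)
        np.testing.assert_allclose(
            leading_order_B(x, p), 1 + 1.4 * (1 - x**2) / 1.4, rtol=1e-12
        )

    def test_branch_continuity(self):
        x = np.linspace(0, 1, 201)
        on = leading_order_B(x, P(l2=2.0, l4=2.0, l5=1.0))
        for sign in (+1, -1):
            off = leading_order_B(x, P(l2=2.0, l4=2.0 * (1 + sign * 1e-6), l5=1.0))
            assert np.max(np.abs(on - off)) < 1e-4


class TestInvariants:
    def test_boundary_and_symmetry(self, rng):
        """Exact boundary value 1; zero centred slope to O(h^2)."""
        h = 1e-6
        for _ in range(20):
            p = random_o1_params(rng)
            A0, B0, C0 = leading_order_profile(np.array([1.0]), p)
            assert A0[0] == pytest.approx(1.0, abs=1e-13)
            assert B0[0] == pytest.approx(1.0, abs=1e-13)
            assert C0[0] == pytest.approx(1.0, abs=1e-13)
            for f in (leading_order_A, leading_order_B, leading_order_C):
                # central difference about x = 0 using evenness: f(h) - f(0)
                slope = (f(h, p) - f(0.0, p)) / h
                assert abs(slope) < 1e-4  # O(h) from the one-sided eval of an even fn

    def test_steady_equation_residual(self, rng):
        """Plugging the closed forms into the leading-order equations via
        central differences gives residual < 1e-6 on a 1e-3 grid."""
        x = np.linspace(0, 1, 1001)
        for _ in range(10):
            p = random_o1_params(rng)
            A0, B0, C0 = leading_order_profile(x, p)
            h2 = 1e-6

            def lap(u):
                return (u[:-2] - 2 * u[1:-1] + u[2:]) / h2

            rA = p.delta_A * lap(A0) + p.lambda2 * p.mu_A * C0[1:-1] - p.lambda3 * A0[1:-1]
            rB = p.delta_B * lap(B0) - p.lambda4 * B0[1:-1] + p.lambda5 * C0[1:-1]
            rC = lap(C0) - p.lambda2 * C0[1:-1]
            for r in (rA, rB, rC):
                assert np.max(np.abs(r)) < 1e-6

    def test_centre_maximum_implies_no_other_stationary_point(self, rng):
        """If x = 0 is a maximum of A0, the profile decays monotonically."""
        x = np.linspace(0, 1, 2001)
        n_centre = 0
        for _ in range(200):
            p = random_o1_params(rng)
            A0 = leading_order_A(x, p)
            if A0[0] >= np.max(A0) and A0[1] < A0[0]:
                n_centre += 1
                assert np.all(np.diff(A0) <= 1e-12)
        assert n_centre > 0  # the sample actually exercised the property

    def test_upper_bound_on_central_concentration(self):
        """For lambda3 = 0, A0(0) <= 1 + mu_A/delta_A, with equality
        approached as lambda2 -> infinity."""
        for muA, dA in ((1.0, 1.0), (100.0, 1.0), (2.0, 0.5)):
            bound = 1 + muA / dA
            vals = [
                central_A0(P(l2=l2, muA=muA, dA=dA))
                for l2 in np.logspace(0, 8, 17)
            ]
            assert np.all(np.asarray(vals) <= bound + 1e-9)
            assert vals[-1] == pytest.approx(bound, rel=1e-3)

    def test_boundary_layer_width_scaling(self):
        """The complex half-value point sits at 1 - x ~ lambda2^(-1/2)."""
        x = np.linspace(0, 1, 200001)
        widths = []
        for l2 in np.logspace(3, 6, 7):
            c = leading_order_C(x, P(l2=l2))
            x_half = np.interp(0.5, c, x)  # C0 is increasing
            widths.append((1 - x_half) * np.sqrt(l2))
        widths = np.asarray(widths)
        # constant (= ln 2 asymptotically) within 5% across three decades
        assert np.max(np.abs(widths / widths[-1] - 1)) < 0.05

    def test_central_A0_non_increasing_in_lambda3(self):
        for l2 in (1.0, 10.0, 50.0):
            vals = [central_A0(P(l2=l2, l3=l3)) for l3 in np.linspace(0, 20, 80)]
            assert np.all(np.diff(vals) <= 1e-12)


class TestSmallLambda1Profile:
    def test_reduces_to_leading_order_at_zero(self):
        x = np.linspace(0, 1, 11)
        p = P(l2=5, l3=0.5, l4=0.2, l5=1)
        exact = leading_order_profile(x, p)
        for got, want in zip(small_lambda1_profile(x, p, 0.0), exact):
            np.testing.assert_array_equal(got, want)

    def test_warns_when_grouping_is_large(self):
        """A small lambda1 with mu_A/delta_A ~ 1e3 still invalidates the
        expansion: the correction grouping is O(100)."""
        p = DimensionlessParameters(0.1, 1, 0.5, 0.1, 12, 10, 0.2, 0.01, 0.1)
        with pytest.warns(ExpansionValidityWarning, match="mu_A/delta_A"):
            small_lambda1_profile(np.linspace(0, 1, 5), p)

    def test_warns_for_large_lambda1(self):
        p = P(l2=5, l3=0.5, l4=0.2, l5=1)
        with pytest.warns(ExpansionValidityWarning, match="not small"):
            small_lambda1_profile(np.linspace(0, 1, 5), p, lambda1=0.5)
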