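"""Semi-implicit time stepper and steady-state certification."""

import numpy as np
import pytest

from tissuetarget import (
    ConcentrationProfile,
    DimensionlessParameters,
    ParameterError,
    SolverConfig,
    SolverInstabilityError,
    build_grid,
    imex_step,
    leading_order_profile,
    run_to_steady,
    steady_residual,
)

from conftest import random_o1_params


def P(l1=0, l2=0, l3=0, l4=0, l5=0, muA=1, muB=1, dA=1, dB=1):
    return DimensionlessParameters(l1, l2, l3, l4, l5, muA, muB, dA, dB)


def uniform_state(config):
    x = build_grid(config)
    ones = np.ones_like(x)
    return ConcentrationProfile(x=x, A=ones, B=ones, C=ones, t=0.0)


class TestGrid:
    def test_examples(self):
        np.testing.assert_allclose(build_grid(SolverConfig(dx=0.5)), [0, 0.5, 1])
        assert build_grid(SolverConfig()).size == 501  # dx = 0.002 default

    def test_incommensurate_dx_rejected(self):
        with pytest.raises(ParameterError, match="divide"):
            SolverConfig(dx=0.3)


class TestStep:
    def test_uniform_equilibrium_is_fixed_point(self):
        config = SolverConfig(dx=0.01)
        state = uniform_state(config)
        nxt = imex_step(state, P(), config)
        np.testing.assert_allclose(nxt.A, 1.0, atol=1e-14)
        np.testing.assert_allclose(nxt.B, 1.0, atol=1e-14)
        np.testing.assert_allclose(nxt.C, 1.0, atol=1e-14)
        assert nxt.t == pytest.approx(config.dt)

    def test_reaction_signs_after_one_step(self):
        """Pure breakdown: the complex is consumed in the interior and the
        released chemical accumulates."""
        config = SolverConfig(dx=0.01)
        state = uniform_state(config)
        nxt = imex_step(state, P(l2=5.0), config)
        assert np.all(nxt.C[:-1] < 1.0)
        assert np.all(nxt.A[:-1] > 1.0)

    def test_first_order_accuracy_in_time(self):
        """Global error at fixed horizon halves with the timestep."""
        p = P(l1=0.5, l2=5, l3=0.5, l4=0.2, l5=1)
        T = 0.1

        def integrate(dt):
            config = SolverConfig(dx=0.02, dt=dt, max_steps=10**6)
            state = uniform_state(config)
            for _ in range(int(round(T / dt))):
                state = imex_step(state, p, config)
            return np.column_stack([state.A, state.B, state.C])

        ref = integrate(T / 512)
        err = [np.max(np.abs(integrate(T / n) - ref)) for n in (8, 16, 32)]
        assert err[0] / err[1] == pytest.approx(2.0, rel=0.3)
        assert err[1] / err[2] == pytest.approx(2.0, rel=0.35)

    def test_instability_is_reported(self):
        """A violently stiff explicit coupling blows up and is caught."""
        p = P(l1=1e8, l2=5, l3=0.5, l4=0.2, l5=1, muA=100, muB=100)
        with pytest.raises(SolverInstabilityError, match="step"):
            run_to_steady(p, SolverConfig(dx=0.01, dt=10.0, max_steps=200))


class TestRunToSteady:
    def test_no_reaction_steady_state_is_uniform(self):
        sol = run_to_steady(P(), SolverConfig(dx=0.01))
        assert sol.converged
        np.testing.assert_allclose(sol.profile.A, 1.0, atol=1e-8)
        np.testing.assert_allclose(sol.profile.B, 1.0, atol=1e-8)
        np.testing.assert_allclose(sol.profile.C, 1.0, atol=1e-8)

    def test_matches_closed_form_at_zero_lambda1(self):
        p = P(l2=50, l3=0.5)
        sol = run_to_steady(p)  # paper grid dx=0.002, dt=0.005
        assert sol.converged
        A0, B0, C0 = leading_order_profile(sol.profile.x, p)
        assert np.max(np.abs(sol.profile.A - A0)) < 1e-3
        assert np.max(np.abs(sol.profile.C - C0)) < 1e-3

    def test_complex_formation_depletes_chemical(self):
        """Raising lambda1 moves A down and C up throughout the interior."""
        base = P(l2=5, l3=0.5, l4=1, l5=1)
        config = SolverConfig(dx=0.004)
        sol0 = run_to_steady(base, config)
        sol2 = run_to_steady(base.with_(lambda1=2.0), config)
        assert np.all(sol2.profile.A[:-1] < sol0.profile.A[:-1])
        assert np.all(sol2.profile.C[:-1] > sol0.profile.C[:-1])

    def test_positivity_along_the_run(self):
        config = SolverConfig(dx=0.01)
        p = P(l1=2, l2=5, l3=0.5, l4=1, l5=1)
        state = uniform_state(config)
        for _ in range(100):
            state = imex_step(state, p, config)
            assert np.all(state.A > 0) and np.all(state.B > 0) and np.all(state.C > 0)

    def test_initial_condition_independence(self):
        """Uniform start and analytic-profile start reach the same state."""
        p = P(l2=5, l3=0.5, l4=0.2, l5=1)
        config = SolverConfig(dx=0.005)
        sol_uniform = run_to_steady(p, config)
        x = build_grid(config)
        A0, B0, C0 = leading_order_profile(x, p)
        init = ConcentrationProfile(x=x, A=A0, B=B0, C=C0, t=0.0)
        sol_analytic = run_to_steady(p, config, init=init)
        for name in ("A", "B", "C"):
            assert np.max(
                np.abs(getattr(sol_uniform.profile, name) - getattr(sol_analytic.profile, name))
            ) < 1e-6

    def test_non_convergence_reported_not_raised(self):
        sol = run_to_steady(P(l2=50, l3=0.5), SolverConfig(dx=0.01, max_steps=5))
        assert not sol.converged
        assert sol.steps_taken == 5
        assert isinstance(sol.profile.t, float)

    def test_grid_convergence_is_second_order(self, rng):
        p = random_o1_params(rng)
        errs = []
        for dx in (0.01, 0.005):
            sol = run_to_steady(p, SolverConfig(dx=dx))
            A0, B0, C0 = leading_order_profile(sol.profile.x, p)
            errs.append(
                max(
                    np.max(np.abs(sol.profile.A - A0)),
                    np.max(np.abs(sol.profile.B - B0)),
                    np.max(np.abs(sol.profile.C - C0)),
                )
            )
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.35)


class TestSteadyResidual:
    def test_uniform_no_reaction_residual_is_zero(self):
        config = SolverConfig(dx=0.01)
        res = steady_residual(uniform_state(config), P())
        assert res == {"A": 0.0, "B": 0.0, "C": 0.0}

    def test_residual_of_closed_form_shrinks_as_dx_squared(self):
        p = P(l2=5, l3=0.5, l4=0.2, l5=1)
        vals = []
        for n in (101, 201):
            x = np.linspace(0, 1, n)
            A0, B0, C0 = leading_order_profile(x, p)
            prof = ConcentrationProfile(x=x, A=A0, B=B0, C=C0)
            vals.append(max(steady_residual(prof, p).values()))
        assert vals[0] / vals[1] == pytest.approx(4.0, rel=0.2)

    def test_perturbation_increases_residual(self):
        p = P(l2=5, l3=0.5, l4=0.2, l5=1)
        sol = run_to_steady(p, SolverConfig(dx=0.01))
        good = max(sol.residual.values())
        bumped = ConcentrationProfile(
            x=sol.profile.x,
            A=sol.profile.A + 1e-3 * np.sin(np.pi * sol.profile.x),
            B=sol.profile.B,
            C=sol.profile.C,
        )
        assert max(steady_residual(bumped, p).values()) > 10 * good

    def test_too_few_nodes_rejected(self):
        x = np.linspace(0, 1, 4)
        prof = ConcentrationProfile(x=x, A=np.ones(4), B=np.ones(4), C=np.ones(4))
        with pytest.raises(ParameterError, match="5"):
            steady_residual(prof, P())
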