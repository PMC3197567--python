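"""Semi-implicit finite-difference solver for the full nonlinear model.

The dimensionless system

    dA/dt = delta_A * A_xx - lambda1*mu_A * A*B + lambda2*mu_A * C - lambda3 * A
    dB/dt = delta_B * B_xx - lambda1*mu_B * A*B - lambda4 * B + lambda5 * C
    dC/dt =           C_xx + lambda1 * A*B - lambda2 * C

is integrated on 0 <= x <= 1 with a reflecting (symmetry) condition at
x = 0, Dirichlet value 1 at x = 1 and the uniform initial state
A = B = C = 1, until the solution stops changing.

Time stepping is IMEX backward Euler: diffusion and each species' own
linear reaction terms are implicit, so the stiff linear part is
unconditionally stable and each species update is one pre-factorised
tridiagonal solve; the bilinear binding term ``lambda1*A*B`` is evaluated
at the current step.  Species are updated in the order C, A, B so the
linear cross-couplings (``lambda2*mu_A*C`` and ``lambda5*C``) use the
freshly updated complex field.  The converged steady state of the scheme
satisfies the time-independent central-difference equations exactly,
independent of the timestep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy.sparse import csc_matrix, diags
from scipy.sparse.linalg import splu

from .params import ConcentrationProfile, DimensionlessParameters, ParameterError

__all__ = [
    "SolverConfig",
    "SteadyStateSolution",
    "SolverInstabilityError",
    "build_grid",
    "imex_step",
    "run_to_steady",
    "steady_residual",
]

logger = logging.getLogger(__name__)


class SolverInstabilityError(RuntimeError):
    """Non-finite values appeared during time stepping."""


@dataclass(frozen=True)
class SolverConfig:
    """Discretisation and stopping settings for the time stepper.

    ``dx`` must divide the unit interval into a whole number of cells so
    that the grid contains x = 0 and x = 1 exactly.  ``steady_tol`` is a
    threshold on the *rate* of change max|u(t+dt) - u(t)| / dt, which
    makes the stopping test independent of the timestep.
    """

    dx: float = 0.002
    dt: float = 0.005
    steady_tol: float = 1e-8
    max_steps: int = 200_000
    report_every: int = 0

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dt > 0 and self.steady_tol > 0):
            raise ParameterError("dx, dt and steady_tol must be positive")
        if self.max_steps < 1:
            raise ParameterError("max_steps must be at least 1")
        n = 1.0 / self.dx
        if abs(n - round(n)) > 1e-8 * n:
            raise ParameterError(
                f"dx = {self.dx} does not divide the unit interval evenly"
            )

    @property
    def n_cells(self) -> int:
        return int(round(1.0 / self.dx))


@dataclass(frozen=True)
class SteadyStateSolution:
    """Outcome of :func:`run_to_steady`.

    ``residual`` holds, per species, the max-norm of the steady equations
    assembled from the final profile by central differences; ``converged``
    requires both the rate-of-change criterion and a residual below
    ``10 * steady_tol`` times the solution scale.
    """

    profile: ConcentrationProfile
    steps_taken: int
    residual: Dict[str, float]
    converged: bool
    final_change_rate: float = float("nan")


def build_grid(config: SolverConfig) -> np.ndarray:
    """Equispaced nodes x_i = i*dx including both endpoints."""
    return np.linspace(0.0, 1.0, config.n_cells + 1)


class _ImexOperator:
    """Pre-factorised backward-Euler operators for the three species."""

    def __init__(self, p: DimensionlessParameters, config: SolverConfig):
        self.p = p
        self.config = config
        self.x = build_grid(config)
        # The Dirichlet node x = 1 is eliminated from the linear systems:
        # its known value enters the last interior row's right-hand side.
        # This keeps the boundary exactly 1 and the interior exactly
        # consistent with it (no rounding mismatch amplified by 1/dx^2).
        n = self.x.size - 1
        dt, dx = config.dt, config.dx
        self._lu = {}
        self._bc = {}
        for name, diff, decay in (
            ("A", p.delta_A, p.lambda3),
            ("B", p.delta_B, p.lambda4),
            ("C", 1.0, p.lambda2),
        ):
            r = dt * diff / dx**2
            main = np.full(n, 1.0 + 2.0 * r + dt * decay)
            lower = np.full(n - 1, -r)
            upper = np.full(n - 1, -r)
            upper[0] = -2.0 * r  # ghost-node reflection: u[-1] = u[1]
            mat = diags([lower, main, upper], [-1, 0, 1], format="csc")
            self._lu[name] = splu(csc_matrix(mat))
            self._bc[name] = r  # coupling of the last interior node to u(1)=1

    def step(self, A: np.ndarray, B: np.ndarray, C: np.ndarray):
        p, dt = self.p, self.config.dt
        # Overflow here means the explicit coupling is unstable; it is
        # detected and reported downstream, so keep numpy quiet.
        with np.errstate(over="ignore", invalid="ignore"):
            return self._step_inner(A, B, C, p, dt)

    def _solve(self, name: str, rhs_interior: np.ndarray) -> np.ndarray:
        rhs_interior[-1] += self._bc[name]
        u = np.empty(rhs_interior.size + 1)
        u[:-1] = self._lu[name].solve(rhs_interior)
        u[-1] = 1.0
        return u

    def _step_inner(self, A, B, C, p, dt):
        AB = A * B
        C_new = self._solve("C", C[:-1] + dt * p.lambda1 * AB[:-1])
        A_new = self._solve(
            "A",
            A[:-1] + dt * (p.lambda2 * p.mu_A * C_new[:-1] - p.lambda1 * p.mu_A * AB[:-1]),
        )
        B_new = self._solve(
            "B",
            B[:-1] + dt * (p.lambda5 * C_new[:-1] - p.lambda1 * p.mu_B * AB[:-1]),
        )
        return A_new, B_new, C_new


def imex_step(
    state: ConcentrationProfile,
    p: DimensionlessParameters,
    config: SolverConfig,
) -> ConcentrationProfile:
    """Advance the state by one IMEX backward-Euler step.

    The state must live on the grid implied by ``config.dx``.  Raises
    :class:`SolverInstabilityError` if non-finite values appear.
    """
    x = build_grid(config)
    if state.x.size != x.size or not np.allclose(state.x, x):
        raise ParameterError("state grid does not match the solver grid")
    op = _ImexOperator(p, config)
    A, B, C = op.step(state.A, state.B, state.C)
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B)) and np.all(np.isfinite(C))):
        raise SolverInstabilityError(
            "non-finite values after one step; reduce dt"
        )
    t = 0.0 if isinstance(state.t, str) else state.t
    return ConcentrationProfile(x=x, A=A, B=B, C=C, t=t + config.dt)


def run_to_steady(
    p: DimensionlessParameters,
    config: Optional[SolverConfig] = None,
    init: Optional[ConcentrationProfile] = None,
) -> SteadyStateSolution:
    """Integrate the full model to steady state.

    Starts from the uniform state A = B = C = 1 (the simplest state
    compatible with the boundary values) unless ``init`` is given, and
    iterates until ``max|change|/dt < steady_tol`` for every species or
    ``max_steps`` is exhausted.  Non-convergence is reported through the
    ``converged`` flag rather than an exception.
    """
    config = config or SolverConfig()
    op = _ImexOperator(p, config)
    x = op.x
    if init is not None:
        if init.x.size != x.size or not np.allclose(init.x, x):
            raise ParameterError("init grid does not match the solver grid")
        A, B, C = init.A.copy(), init.B.copy(), init.C.copy()
    else:
        A = np.ones_like(x)
        B = np.ones_like(x)
        C = np.ones_like(x)

    dt = config.dt
    change_rate = float("inf")
    converged = False
    step = 0
    for step in range(1, config.max_steps + 1):
        A_new, B_new, C_new = op.step(A, B, C)
        if not np.all(np.isfinite(C_new)) or not np.all(np.isfinite(A_new)) or not np.all(
            np.isfinite(B_new)
        ):
            raise SolverInstabilityError(
                f"non-finite values at step {step}; reduce dt"
            )
        change_rate = (
            max(
                np.max(np.abs(A_new - A)),
                np.max(np.abs(B_new - B)),
                np.max(np.abs(C_new - C)),
            )
            / dt
        )
        A, B, C = A_new, B_new, C_new
        if config.report_every and step % config.report_every == 0:
            logger.info("step %d: max|change|/dt = %.3e", step, change_rate)
        if change_rate < config.steady_tol:
            converged = True
            break

    profile = ConcentrationProfile(x=x, A=A, B=B, C=C, t="steady" if converged else step * dt)
    residual = steady_residual(profile, p)
    if converged:
        scale = max(1.0, float(np.max(np.abs(A))), float(np.max(np.abs(B))), float(np.max(np.abs(C))))
        converged = max(residual.values()) <= 10.0 * config.steady_tol * scale
    return SteadyStateSolution(
        profile=profile,
        steps_taken=step,
        residual=residual,
        converged=converged,
        final_change_rate=change_rate,
    )


def steady_residual(
    profile: ConcentrationProfile, p: DimensionlessParameters
) -> Dict[str, float]:
    """Max-norm residuals of the steady equations over interior nodes.

    Central second differences on the profile's (uniform) grid; the
    boundary rows are excluded.  A converged solver output satisfies these
    equations to roughly the stopping tolerance, because the implicit
    scheme's fixed point *is* the central-difference steady state.
    """
    x = profile.x
    if x.size < 5:
        raise ParameterError("steady_residual needs at least 5 grid nodes")
    dx = np.diff(x)
    if not np.allclose(dx, dx[0], rtol=1e-8):
        raise ParameterError("steady_residual requires a uniform grid")
    h2 = dx[0] ** 2

    def lap(u):
        return (u[:-2] - 2.0 * u[1:-1] + u[2:]) / h2

    A, B, C = profile.A, profile.B, profile.C
    Ai, Bi, Ci = A[1:-1], B[1:-1], C[1:-1]
    AB = Ai * Bi
    rA = p.delta_A * lap(A) - p.lambda1 * p.mu_A * AB + p.lambda2 * p.mu_A * Ci - p.lambda3 * Ai
    rB = p.delta_B * lap(B) - p.lambda1 * p.mu_B * AB - p.lambda4 * Bi + p.lambda5 * Ci
    rC = lap(C) + p.lambda1 * AB - p.lambda2 * Ci
    return {
        "A": float(np.max(np.abs(rA))),
        "B": float(np.max(np.abs(rB))),
        "C": float(np.max(np.abs(rC))),
    }
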