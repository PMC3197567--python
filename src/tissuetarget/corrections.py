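"""First-order corrections in the complex-formation rate.

At O(lambda1) the expansion of the steady state produces a linear system
for the corrections (A1, B1, C1), forced by the product ``A0*B0`` of the
leading-order profiles:

    delta_A * A1'' - mu_A * A0*B0 + lambda2*mu_A * C1 - lambda3 * A1 = 0
    delta_B * B1'' - mu_B * A0*B0 - lambda4 * B1 + lambda5 * C1      = 0
              C1'' +        A0*B0 - lambda2 * C1                     = 0

with symmetry conditions ``A1' = B1' = C1' = 0`` at ``x = 0`` and
``A1 = B1 = C1 = 0`` at ``x = 1``.  Because ``A0`` and ``B0`` are sums of
two cosh modes, the forcing expands into cosh modes with the six combined
wavenumbers ``theta_j`` plus a ``2*sqrt(lambda2)`` mode and a constant,
and the whole system solves in closed form.

The coefficients returned by :func:`correction_coefficients` are derived
from this ODE system directly (not transcribed from any tabulation) and
are certified by :func:`correction_residual`, which evaluates the three
equations with *analytic* second derivatives: the residual of a correct
coefficient set is at the rounding level.  An independent second-order
finite-difference solve of the same system, :func:`correction_oracle_bvp`,
provides a purely numerical cross-check and takes over on the resonance
loci where a closed-form denominator vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.linalg import solve_banded

from .analytic import _check_x, leading_order_A, leading_order_B
from .params import DimensionlessParameters

__all__ = [
    "CorrectionCoefficients",
    "CorrectionProfiles",
    "DegenerateModeError",
    "correction_coefficients",
    "first_order_correction",
    "correction_oracle_bvp",
    "correction_residual",
]

#: Relative threshold on closed-form denominators below which a parameter
#: set is treated as sitting on a resonance locus (e.g. theta_j**2 equal to
#: lambda3/delta_A, lambda4/delta_B or lambda2) and the numerical fallback
#: is used instead of the limiting closed form.
EPS_RESONANCE = 1e-8


class DegenerateModeError(ValueError):
    """A closed-form denominator vanishes (resonant mode combination).

    The parameter set lies on (or within ``EPS_RESONANCE`` of) a locus
    where two cosh modes coincide and the generic coefficients blow up.
    Evaluate the correction with :func:`correction_oracle_bvp` (done
    automatically by :func:`first_order_correction`), which handles these
    loci without case-by-case limits.
    """

    def __init__(self, loci):
        self.loci = list(loci)
        super().__init__(
            "correction coefficients are degenerate near the resonance "
            "locus/loci: " + ", ".join(self.loci) + "; use the numerical "
            "boundary-value evaluation (correction_oracle_bvp) instead"
        )


class CorrectionProfiles(NamedTuple):
    """Numerically evaluated correction profiles on a grid."""

    x: np.ndarray
    A1: np.ndarray
    B1: np.ndarray
    C1: np.ndarray


@dataclass(frozen=True)
class CorrectionCoefficients:
    """Closed-form amplitudes of the O(lambda1) correction terms.

    ``theta`` holds the six combined wavenumbers (sums and differences of
    the homogeneous wavenumbers ``sqrt(lambda3/delta_A)``,
    ``sqrt(lambda4/delta_B)`` and ``sqrt(lambda2)``); ``beta`` the four
    leading-order mode amplitudes whose pairwise products force the
    correction system.  ``A_star``/``B_star``/``C_star`` are the
    homogeneous amplitudes fixed by the zero boundary condition at
    ``x = 1``; ``A`` (8 entries), ``B`` (9) and ``C`` (8) the particular
    amplitudes.  ``modes_A``/``modes_B``/``modes_C`` list each species'
    full set of wavenumbers in the same order as the concatenated
    amplitude vectors ``[X_star, X_1, ..., X_n]``.
    """

    theta: np.ndarray
    beta: np.ndarray
    A_star: float
    A: np.ndarray
    B_star: float
    B: np.ndarray
    C_star: float
    C: np.ndarray
    modes_A: np.ndarray
    modes_B: np.ndarray
    modes_C: np.ndarray

    def _amps(self, species: str) -> np.ndarray:
        star = getattr(self, f"{species}_star")
        return np.concatenate(([star], getattr(self, species)))

    def _sum_modes(self, species: str, x, second_derivative: bool = False):
        x = np.atleast_1d(_check_x(x))
        amps = self._amps(species)
        ks = getattr(self, f"modes_{species}")
        terms = np.cosh(np.outer(ks, x))
        if second_derivative:
            terms = terms * (ks**2)[:, None]
        return amps @ terms

    def evaluate(self, x):
        """Evaluate (A1, B1, C1) at positions ``x``."""
        return tuple(self._sum_modes(sp, x) for sp in ("A", "B", "C"))

    def evaluate_d2(self, x):
        """Analytic second derivatives (A1'', B1'', C1'') at ``x``."""
        return tuple(
            self._sum_modes(sp, x, second_derivative=True) for sp in ("A", "B", "C")
        )


def correction_coefficients(
    p: DimensionlessParameters, eps_res: float = EPS_RESONANCE
) -> CorrectionCoefficients:
    """Derive the closed-form amplitudes of the O(lambda1) corrections.

    The derivation proceeds species by species.  The forcing
    ``A0*B0 = (b1*cosh(kA x) + b2*cosh(s x)) * (b3*cosh(kB x) + b4*cosh(s x))``
    is expanded with the product-to-sum identity into modes with
    wavenumbers ``theta_1..theta_6``, ``2s`` and ``0``.  The complex
    correction C1 is solved first; its modes then join the forcing of the
    A1 and B1 equations.  Each particular amplitude is the forcing
    amplitude divided by ``(wavenumber**2 - homogeneous rate)`` for the
    species at hand, and each homogeneous amplitude is fixed by the zero
    Dirichlet condition at ``x = 1``.  In the free-chemical equation the
    constant forcing modes cancel identically (``f8 - lambda2*C8 = 0``),
    so A1 carries no constant term.

    Raises
    ------
    DegenerateModeError
        If any denominator lies within ``eps_res`` (relatively) of zero —
        the resonance loci where the generic closed form is invalid.
    """
    lam2, lam3, lam4, lam5 = p.lambda2, p.lambda3, p.lambda4, p.lambda5
    dA, dB, muA, muB = p.delta_A, p.delta_B, p.mu_A, p.mu_B

    s = np.sqrt(lam2)
    kA = np.sqrt(lam3 / dA)
    kB = np.sqrt(lam4 / dB)
    theta = np.array([kA + kB, kA - kB, kA + s, kA - s, kB + s, kB - s])

    loci = []

    def _checked(value: float, label: str, *scale_terms: float) -> float:
        scale = max(1.0, *(abs(t) for t in scale_terms)) if scale_terms else 1.0
        if abs(value) <= eps_res * scale:
            loci.append(label)
        return value

    den_A = _checked(dA * lam2 - lam3, "delta_A*lambda2 = lambda3", dA * lam2, lam3)
    den_B = _checked(dB * lam2 - lam4, "delta_B*lambda2 = lambda4", dB * lam2, lam4)
    _checked(lam2, "lambda2 = 0", 1.0)
    _checked(lam4, "lambda4 = 0", 1.0)
    th2 = theta**2
    for j in range(6):
        _checked(th2[j] - lam2, f"theta{j + 1}**2 = lambda2", th2[j], lam2)
        _checked(
            dA * th2[j] - lam3, f"theta{j + 1}**2 = lambda3/delta_A", dA * th2[j], lam3
        )
        _checked(
            dB * th2[j] - lam4, f"theta{j + 1}**2 = lambda4/delta_B", dB * th2[j], lam4
        )
    _checked(4 * dA * lam2 - lam3, "4*lambda2 = lambda3/delta_A", 4 * dA * lam2, lam3)
    _checked(4 * dB * lam2 - lam4, "4*lambda2 = lambda4/delta_B", 4 * dB * lam2, lam4)
    if loci:
        raise DegenerateModeError(dict.fromkeys(loci))  # deduplicate, keep order

    # Leading-order mode amplitudes: A0 = beta1*cosh(kA x) + beta2*cosh(s x),
    # B0 = beta3*cosh(kB x) + beta4*cosh(s x).
    beta1 = (1.0 + muA * lam2 / den_A) / np.cosh(kA)
    beta2 = -muA * lam2 / den_A / np.cosh(s)
    beta3 = (1.0 + lam5 / den_B) / np.cosh(kB)
    beta4 = -lam5 / den_B / np.cosh(s)
    beta = np.array([beta1, beta2, beta3, beta4])

    # Forcing amplitudes of A0*B0 on the theta modes, the 2s mode and the
    # constant: cosh(a x)*cosh(b x) = (cosh((a+b)x) + cosh((a-b)x)) / 2.
    f = 0.5 * np.array(
        [
            beta1 * beta3,
            beta1 * beta3,
            beta1 * beta4,
            beta1 * beta4,
            beta2 * beta3,
            beta2 * beta3,
        ]
    )
    f7 = 0.5 * beta2 * beta4  # cosh(2s x) mode
    f8 = 0.5 * beta2 * beta4  # constant mode

    # --- complex correction: C1'' - lambda2*C1 = -A0*B0 -------------------
    C = np.empty(8)
    C[:6] = -f / (th2 - lam2)
    C[6] = -f7 / (3.0 * lam2)  # (2s)**2 - lambda2 = 3*lambda2
    C[7] = f8 / lam2
    C_star = -(
        C[:6] @ np.cosh(theta) + C[6] * np.cosh(2 * s) + C[7]
    ) / np.cosh(s)

    # --- free chemical: delta_A*A1'' - lambda3*A1 = mu_A*(A0*B0 - lambda2*C1)
    A = np.empty(8)
    A[:6] = -muA * C[:6] * th2 / (dA * th2 - lam3)
    A[6] = -muA * C[6] * 4.0 * lam2 / (4.0 * dA * lam2 - lam3)
    A[7] = -muA * lam2 * C_star / den_A  # cosh(s x) mode from the C1 homogeneous term
    # Constant forcing cancels: mu_A*(f8 - lambda2*C8) == 0 exactly.
    A_star = -(
        A[:6] @ np.cosh(theta) + A[6] * np.cosh(2 * s) + A[7] * np.cosh(s)
    ) / np.cosh(kA)

    # --- binding partner: delta_B*B1'' - lambda4*B1 = mu_B*A0*B0 - lambda5*C1
    B = np.empty(9)
    B[:6] = (muB * f - lam5 * C[:6]) / (dB * th2 - lam4)
    B[6] = (muB * f7 - lam5 * C[6]) / (4.0 * dB * lam2 - lam4)
    B[7] = -(muB * f8 - lam5 * C[7]) / lam4  # constant mode
    B[8] = -lam5 * C_star / den_B  # cosh(s x) mode
    B_star = -(
        B[:6] @ np.cosh(theta)
        + B[6] * np.cosh(2 * s)
        + B[7]
        + B[8] * np.cosh(s)
    ) / np.cosh(kB)

    return CorrectionCoefficients(
        theta=theta,
        beta=beta,
        A_star=float(A_star),
        A=A,
        B_star=float(B_star),
        B=B,
        C_star=float(C_star),
        C=C,
        modes_A=np.concatenate(([kA], theta, [2 * s, s])),
        modes_B=np.concatenate(([kB], theta, [2 * s, 0.0, s])),
        modes_C=np.concatenate(([s], theta, [2 * s, 0.0])),
    )


def correction_residual(x, p: DimensionlessParameters):
    """Residuals of the O(lambda1) system for the closed-form corrections.

    Evaluates the three correction equations at ``x`` using analytic
    second derivatives of the cosh-mode sums, so the only error is from
    the coefficients themselves: a correctly derived set gives residuals
    at the floating-point rounding level.  Returns ``(rA, rB, rC)``.
    """
    x = np.atleast_1d(_check_x(x))
    coeffs = correction_coefficients(p)
    A1, B1, C1 = coeffs.evaluate(x)
    d2A, d2B, d2C = coeffs.evaluate_d2(x)
    F = leading_order_A(x, p) * leading_order_B(x, p)
    rA = p.delta_A * d2A - p.mu_A * F + p.lambda2 * p.mu_A * C1 - p.lambda3 * A1
    rB = p.delta_B * d2B - p.mu_B * F - p.lambda4 * B1 + p.lambda5 * C1
    rC = d2C + F - p.lambda2 * C1
    return rA, rB, rC


def _solve_modified_helmholtz(q: float, rhs: np.ndarray, dx: float) -> np.ndarray:
    """Solve u'' - q*u = rhs on a uniform grid over [0, 1].

    Second-order central differences; the symmetry condition u'(0) = 0 is
    imposed through a reflected ghost node and u = 0 at x = 1.
    """
    n = rhs.size
    inv_dx2 = 1.0 / dx**2
    ab = np.zeros((3, n))
    ab[0, 1:] = inv_dx2  # upper diagonal
    ab[1, :] = -2.0 * inv_dx2 - q  # main diagonal
    ab[2, :-1] = inv_dx2  # lower diagonal
    ab[0, 1] = 2.0 * inv_dx2  # ghost-node reflection at x = 0
    ab[1, -1] = 1.0  # Dirichlet row at x = 1
    ab[2, -2] = 0.0
    b = rhs.copy()
    b[-1] = 0.0
    return solve_banded((1, 1), ab, b)


def _oracle_on_grid(p: DimensionlessParameters, x: np.ndarray) -> CorrectionProfiles:
    dx = x[1] - x[0]
    F = leading_order_A(x, p) * leading_order_B(x, p)
    C1 = _solve_modified_helmholtz(p.lambda2, -F, dx)
    A1 = _solve_modified_helmholtz(
        p.lambda3 / p.delta_A,
        p.mu_A / p.delta_A * (F - p.lambda2 * C1),
        dx,
    )
    B1 = _solve_modified_helmholtz(
        p.lambda4 / p.delta_B,
        (p.mu_B * F - p.lambda5 * C1) / p.delta_B,
        dx,
    )
    return CorrectionProfiles(x=x, A1=A1, B1=B1, C1=C1)


def correction_oracle_bvp(
    p: DimensionlessParameters,
    n_nodes: int = 2001,
    richardson: bool = False,
) -> CorrectionProfiles:
    """Numerical solve of the O(lambda1) correction system.

    A second-order finite-difference discretisation of the linear
    boundary-value system on ``n_nodes`` equispaced nodes.  The three
    equations decouple sequentially (C1 first, then A1 and B1), so each
    solve is a single tridiagonal system.  This route makes no use of the
    closed-form coefficients and serves as their independent certification;
    it is also the evaluation path on the resonance loci, where it needs
    no special-casing.

    With ``richardson=True`` the solve is repeated on a doubled grid and
    Richardson-extrapolated, cancelling the leading O(dx^2) error term.
    """
    if n_nodes < 5:
        raise ValueError("n_nodes must be at least 5")
    x = np.linspace(0.0, 1.0, n_nodes)
    coarse = _oracle_on_grid(p, x)
    if not richardson:
        return coarse
    fine = _oracle_on_grid(p, np.linspace(0.0, 1.0, 2 * n_nodes - 1))
    out = [(4.0 * f[::2] - c) / 3.0 for c, f in zip(coarse[1:], fine[1:])]
    return CorrectionProfiles(x, *out)


def first_order_correction(x, p: DimensionlessParameters):
    """Evaluate the O(lambda1) corrections (A1, B1, C1) at positions ``x``.

    Uses the closed-form cosh-mode sums away from the resonance loci; on
    (or numerically near) a locus it falls back to the Richardson-
    extrapolated boundary-value solve, interpolated onto ``x``.  All three
    corrections vanish at ``x = 1`` and have zero slope at ``x = 0``.
    """
    x = np.atleast_1d(_check_x(x))
    try:
        coeffs = correction_coefficients(p)
    except DegenerateModeError:
        prof = correction_oracle_bvp(p, n_nodes=4001, richardson=True)
        return tuple(np.interp(x, prof.x, u) for u in (prof.A1, prof.B1, prof.C1))
    return coeffs.evaluate(x)
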