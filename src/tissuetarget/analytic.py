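"""Closed-form steady states for a slowly forming complex.

When the dimensionless complex-formation rate ``lambda1`` is small the
steady state of the model admits a regular perturbation expansion

    A_S = A0(x) + lambda1 * A1(x) + ...,

and likewise for B_S and C_S.  The leading-order terms satisfy a linear
system whose solution is a combination of hyperbolic cosines; this module
evaluates those closed forms, including the degenerate branches that arise
when the homogeneous and particular wavenumbers coincide, and assembles
the truncated two-term expansion.

All evaluation goes through :func:`cosh_ratio`, an overflow-safe form of
``cosh(k*x) / cosh(k)`` that remains accurate for very stiff breakdown
rates (``lambda2`` up to ~1e12), where the complex is confined to a
boundary layer of width ``O(lambda2**-0.5)`` at the tissue edge.
"""

from __future__ import annotations

import warnings

import numpy as np

from .params import DimensionlessParameters

__all__ = [
    "cosh_ratio",
    "sinh_over_cosh",
    "leading_order_A",
    "leading_order_B",
    "leading_order_C",
    "leading_order_profile",
    "central_A0",
    "small_lambda1_profile",
    "ExpansionValidityWarning",
]

# Relative threshold below which a vanishing branch denominator is treated
# as exactly degenerate (the two cosh modes coincide and the resonant
# x*sinh form applies).
_BRANCH_TOL = 1e-9


class ExpansionValidityWarning(UserWarning):
    """The small-``lambda1`` expansion is being used outside its regime.

    The expansion assumes ``lambda1 << 1`` with every other group O(1).
    It is the *groupings* ``lambda1 * mu_A / delta_A`` and
    ``lambda1 * mu_B / delta_B`` that enter the correction terms, so a
    small ``lambda1`` paired with a large concentration or small
    diffusivity ratio can still invalidate the truncation.
    """


def _check_x(x):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise ValueError("position x must lie in [0, 1]")
    return x


def cosh_ratio(k: float, x) -> np.ndarray:
    """Evaluate ``cosh(k*x) / cosh(k)`` without overflow.

    Uses the identity

        cosh(k*x)/cosh(k) = exp(k*(x-1)) * (1 + exp(-2*k*x)) / (1 + exp(-2*k))

    in which every exponent is nonpositive for ``k >= 0`` and ``x`` in
    [0, 1], so arbitrarily large wavenumbers are representable.  The ratio
    equals 1 at ``x = 1`` for any ``k`` and is identically 1 for ``k = 0``.
    """
    x = _check_x(x)
    k = abs(float(k))  # cosh is even; accept either sign of the wavenumber
    return np.exp(k * (x - 1.0)) * (1.0 + np.exp(-2.0 * k * x)) / (
        1.0 + np.exp(-2.0 * k)
    )


def sinh_over_cosh(k: float, x) -> np.ndarray:
    """Evaluate ``sinh(k*x) / cosh(k)`` without overflow (``k >= 0``)."""
    x = _check_x(x)
    k = float(k)
    if k < 0:
        raise ValueError("wavenumber k must be nonnegative")
    return np.exp(k * (x - 1.0)) * (1.0 - np.exp(-2.0 * k * x)) / (
        1.0 + np.exp(-2.0 * k)
    )


def leading_order_C(x, p: DimensionlessParameters) -> np.ndarray:
    """Leading-order complex profile ``C0 = cosh(sqrt(lambda2)*x)/cosh(sqrt(lambda2))``.

    The complex enters only at the boundary and is destroyed throughout
    the tissue, so ``C0`` decays monotonically from 1 at ``x = 1`` towards
    the centre, steeply so for fast breakdown (large ``lambda2``).
    """
    return cosh_ratio(np.sqrt(p.lambda2), x)


def _two_mode_solution(x, k_hom: float, s: float, alpha: float) -> np.ndarray:
    """Solution (1 + alpha)*R(k_hom, x) - alpha*R(s, x) of the generic
    leading-order equation, where R is :func:`cosh_ratio`."""
    return (1.0 + alpha) * cosh_ratio(k_hom, x) - alpha * cosh_ratio(s, x)


def _resonant_solution(x, s: float, q: float) -> np.ndarray:
    """Degenerate branch when the homogeneous wavenumber equals sqrt(lambda2).

    Solves u'' - s^2 u = -(2*q*s^2) * cosh(s x)/cosh(s) with u'(0)=0, u(1)=1:

        u = (1 + q*s*tanh(s)) * cosh(s x)/cosh(s) - q*s * x*sinh(s x)/cosh(s)

    written with the forcing amplitude folded into ``q`` so that the free
    chemical uses ``q = mu_A/(2*delta_A)`` and the binding partner
    ``q = lambda5/(2*delta_B*lambda2)``.
    """
    x = _check_x(x)
    if s < 1e-8:
        # Joint limit s -> 0 of the resonant branch: a parabola (for the
        # free chemical the forcing also vanishes and q*s**2 -> 0).
        return 1.0 + q * s**2 * (1.0 - x**2)
    return (1.0 + q * s * np.tanh(s)) * cosh_ratio(s, x) - q * s * x * sinh_over_cosh(
        s, x
    )


def leading_order_A(x, p: DimensionlessParameters) -> np.ndarray:
    """Leading-order free-chemical profile A0.

    Regular branch (``delta_A*lambda2 != lambda3``):

        A0 = (1 + g) * cosh(kA x)/cosh(kA) - g * cosh(s x)/cosh(s)

    with ``kA = sqrt(lambda3/delta_A)``, ``s = sqrt(lambda2)`` and
    ``g = mu_A*lambda2 / (delta_A*lambda2 - lambda3)``.  On the resonance
    locus ``delta_A*lambda2 = lambda3`` the degenerate ``x*sinh`` branch
    applies.  With no breakdown and no removal (``lambda2 = lambda3 = 0``)
    the equation is unforced and ``A0`` is identically 1.
    """
    lam2, lam3 = p.lambda2, p.lambda3
    dA, muA = p.delta_A, p.mu_A
    x = _check_x(x)
    if lam2 == 0.0 and lam3 == 0.0:
        return np.ones_like(x)
    den = dA * lam2 - lam3
    scale = max(1.0, dA * lam2, lam3)
    if abs(den) <= _BRANCH_TOL * scale:
        return _resonant_solution(x, np.sqrt(lam2), muA / (2.0 * dA))
    return _two_mode_solution(x, np.sqrt(lam3 / dA), np.sqrt(lam2), muA * lam2 / den)


def leading_order_B(x, p: DimensionlessParameters) -> np.ndarray:
    """Leading-order binding-partner profile B0.

    Mirrors :func:`leading_order_A` with ``(lambda4, lambda5, delta_B)``
    in place of ``(lambda3, mu_A*lambda2, delta_A)``: the source of *b*
    is complex dissociation at rate ``lambda5`` rather than the full
    breakdown term.  With ``lambda2 = lambda4 = 0`` but ``lambda5 > 0``
    the complex is uniform and undepleted, so B0 is the parabola
    ``1 + lambda5*(1 - x^2)/(2*delta_B)``.
    """
    lam2, lam4, lam5 = p.lambda2, p.lambda4, p.lambda5
    dB = p.delta_B
    x = _check_x(x)
    if lam2 == 0.0 and lam4 == 0.0:
        if lam5 == 0.0:
            return np.ones_like(x)
        return 1.0 + lam5 * (1.0 - x**2) / (2.0 * dB)
    den = dB * lam2 - lam4
    scale = max(1.0, dB * lam2, lam4)
    if abs(den) <= _BRANCH_TOL * scale:
        s = np.sqrt(lam2)
        if s < 1e-8:
            # lambda2 ~ lambda4 ~ 0 with a finite source: parabolic limit.
            return 1.0 + lam5 * (1.0 - x**2) / (2.0 * dB)
        return _resonant_solution(x, s, lam5 / (2.0 * dB * lam2))
    return _two_mode_solution(x, np.sqrt(lam4 / dB), np.sqrt(lam2), lam5 / den)


def leading_order_profile(x, p: DimensionlessParameters):
    """Evaluate (A0, B0, C0) on a grid."""
    return leading_order_A(x, p), leading_order_B(x, p), leading_order_C(x, p)


def central_A0(p: DimensionlessParameters) -> float:
    """Leading-order free-chemical concentration at the tissue centre.

    This is the figure of merit for targeting: it is maximised by slow
    removal (small ``lambda3``) and fast complex breakdown (large
    ``lambda2``), and saturates at ``1 + mu_A/delta_A`` in the limit of
    instantaneous breakdown, when supply of complex by diffusion becomes
    limiting.
    """
    return float(leading_order_A(0.0, p))


def check_expansion_validity(p: DimensionlessParameters, lambda1: float) -> list:
    """Warn when the two-term expansion is outside its regime of validity.

    Returns the list of warning messages issued (empty when the truncation
    is expected to be accurate).
    """
    messages = []
    if lambda1 > 0.1:
        messages.append(
            f"lambda1 = {lambda1:g} is not small; the two-term expansion "
            "in lambda1 may be inaccurate."
        )
    for name, group in (
        ("lambda1*mu_A/delta_A", lambda1 * p.mu_A / p.delta_A),
        ("lambda1*mu_B/delta_B", lambda1 * p.mu_B / p.delta_B),
    ):
        if group > 0.1:
            messages.append(
                f"{name} = {group:g} exceeds 0.1: the correction term is "
                "not uniformly small and the expansion may fail even "
                "though lambda1 itself is small."
            )
    for m in messages:
        warnings.warn(m, ExpansionValidityWarning, stacklevel=3)
    return messages


def small_lambda1_profile(x, p: DimensionlessParameters, lambda1: float | None = None):
    """Two-term steady-state expansion (A0 + lambda1*A1, ...).

    Parameters
    ----------
    x : array_like
        Positions in [0, 1].
    p : DimensionlessParameters
        Parameter set; every group except ``lambda1`` should be O(1).
    lambda1 : float, optional
        Expansion parameter; defaults to ``p.lambda1``.

    Returns
    -------
    (A, B, C) : tuple of ndarray
        The truncated expansion evaluated at ``x``.  For ``lambda1 = 0``
        this is exactly the leading-order solution.

    Warns
    -----
    ExpansionValidityWarning
        When ``lambda1 > 0.1`` or one of the groupings
        ``lambda1*mu_A/delta_A``, ``lambda1*mu_B/delta_B`` exceeds 0.1.
    """
    if lambda1 is None:
        lambda1 = p.lambda1
    if lambda1 < 0:
        raise ValueError("lambda1 must be nonnegative")
    x = _check_x(x)
    A0, B0, C0 = leading_order_profile(x, p)
    if lambda1 == 0.0:
        return A0, B0, C0
    check_expansion_validity(p, lambda1)
    from .corrections import first_order_correction

    A1, B1, C1 = first_order_correction(x, p)
    return A0 + lambda1 * A1, B0 + lambda1 * B1, C0 + lambda1 * C1
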