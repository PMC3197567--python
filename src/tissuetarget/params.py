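"""Parameter spaces of the three-species binding/transport model.

The model tracks a free chemical *a* (e.g. IGF, or the activated form of a
prodrug), its binding partner *b* (e.g. IGFBP3, or an inert by-product of
prodrug activation) and their complex *c* inside a slab of tissue.  All
three species diffuse; *a* and *b* associate reversibly into *c*, the
complex is cleaved inside the tissue to release *a*, and *a* and *b* are
removed at first-order rates.

Two descriptions of the system are supported:

* :class:`DimensionalParameters` — physical rates and diffusivities in CGS/
  molar units, plus the fixed boundary concentrations.
* :class:`DimensionlessParameters` — the nine dimensionless groups obtained
  by scaling space with the tissue half-width ``L``, time with the complex
  diffusion time ``L**2 / D_C`` and each concentration with its boundary
  value.

:func:`nondimensionalise` maps the first onto the second;
:func:`redimensionalise` restores physical units to a computed profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Union

import numpy as np

__all__ = [
    "DimensionalParameters",
    "DimensionlessParameters",
    "ConcentrationProfile",
    "PhysicalConcentrationProfile",
    "ParameterError",
    "ZeroCouplingWarning",
    "nondimensionalise",
    "redimensionalise",
    "nondimensionalise_profile",
]


class ParameterError(ValueError):
    """A parameter set violates the model's validity constraints."""


class ZeroCouplingWarning(UserWarning):
    """The binding-partner coupling ratio mu_B is zero.

    With ``mu_B = 0`` the complex-formation term drops out of the
    binding-partner equation entirely.  The configuration is accepted
    (it appears in published counterexamples probing the limits of the
    small-``lambda1`` expansion) but is flagged because it sits outside
    the strictly positive parameter space of the physical model.
    """


_NONNEGATIVE_DIM = {"k_minus1", "k_minus2", "alpha1", "alpha2"}


@dataclass(frozen=True)
class DimensionalParameters:
    """Physical parameters of the dimensional model.

    Parameters
    ----------
    D_A, D_B, D_C
        Diffusivities of the free chemical, binding partner and complex
        (cm^2 s^-1).  All strictly positive.
    k_plus1
        Association rate of a + b -> c (M^-1 s^-1), strictly positive.
    k_minus1
        Dissociation rate of c -> a + b (s^-1), may be zero.
    k_minus2
        Cleavage rate of c -> a (binding partner destroyed; s^-1), may be
        zero.
    alpha1, alpha2
        First-order removal rates of a and b (s^-1), may be zero.
    L
        Tissue half-width (cm), strictly positive.
    A_star, B_star, C_star
        Boundary concentrations of a, b, c (M), strictly positive: the
        scaling of the problem divides by them.
    """

    D_A: float
    D_B: float
    D_C: float
    k_plus1: float
    k_minus1: float
    k_minus2: float
    alpha1: float
    alpha2: float
    L: float
    A_star: float
    B_star: float
    C_star: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ParameterError(f"{f.name} must be finite, got {v!r}")
            if f.name in _NONNEGATIVE_DIM:
                if v < 0:
                    raise ParameterError(f"{f.name} must be >= 0, got {v!r}")
            elif v <= 0:
                raise ParameterError(f"{f.name} must be > 0, got {v!r}")


@dataclass(frozen=True)
class DimensionlessParameters:
    """The nine dimensionless groups governing the scaled model.

    ``lambda1 .. lambda5`` are ratios of the complex diffusion timescale
    ``L**2 / D_C`` to the reaction timescales:

    * ``lambda1`` — complex formation,
    * ``lambda2`` — total complex breakdown (release of *a*),
    * ``lambda3`` — removal of *a*,
    * ``lambda4`` — removal of *b*,
    * ``lambda5`` — complex dissociation scaled for the *b* equation.

    ``delta_A`` and ``delta_B`` are the diffusivity ratios ``D_A / D_C``
    and ``D_B / D_C``; ``mu_A = C*/A*`` and ``mu_B = C*/B*`` are the
    boundary-concentration ratios coupling the complex to the other two
    species.
    """

    lambda1: float
    lambda2: float
    lambda3: float
    lambda4: float
    lambda5: float
    mu_A: float
    mu_B: float
    delta_A: float
    delta_B: float

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "lambda3", "lambda4", "lambda5"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be finite and >= 0, got {v!r}")
        for name in ("mu_A", "delta_A", "delta_B"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be finite and > 0, got {v!r}")
        v = self.mu_B
        if not np.isfinite(v) or v < 0:
            raise ParameterError(f"mu_B must be finite and >= 0, got {v!r}")
        if v == 0:
            warnings.warn(
                "mu_B = 0 removes complex formation from the binding-partner "
                "equation; proceeding, but this lies outside the strictly "
                "positive physical parameter space.",
                ZeroCouplingWarning,
                stacklevel=3,
            )

    def with_(self, **changes) -> "DimensionlessParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class ConcentrationProfile:
    """Dimensionless concentration profiles on the half-domain [0, 1].

    ``x`` is a strictly increasing grid with ``x[0] == 0`` and
    ``x[-1] == 1``; ``A``, ``B`` and ``C`` hold the concentrations of the
    free chemical, binding partner and complex relative to their boundary
    values.  ``t`` is the elapsed dimensionless time, or the string
    ``"steady"`` for a steady state.
    """

    x: np.ndarray
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    t: Union[float, str] = "steady"

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        for name in ("A", "B", "C"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != self.x.shape:
                raise ParameterError(
                    f"{name} has shape {arr.shape}, expected {self.x.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ParameterError(f"{name} contains non-finite values")
        x = self.x
        if x.ndim != 1 or x.size < 2:
            raise ParameterError("x must be a 1-d grid with at least two nodes")
        # Snap endpoints that are merely a rounding error away from {0, 1},
        # e.g. after a redimensionalise/nondimensionalise round trip.
        if x[0] != 0.0 and abs(x[0]) < 1e-12:
            x = x.copy()
            x[0] = 0.0
            object.__setattr__(self, "x", x)
        if x[-1] != 1.0 and abs(x[-1] - 1.0) < 1e-12:
            x = x.copy()
            x[-1] = 1.0
            object.__setattr__(self, "x", x)
        if not (x[0] == 0.0 and x[-1] == 1.0):
            raise ParameterError("x must span [0, 1] exactly")
        if not np.all(np.diff(x) > 0):
            raise ParameterError("x must be strictly increasing")
        if isinstance(self.t, str):
            if self.t != "steady":
                raise ParameterError("t must be a number or the marker 'steady'")
        elif not np.isfinite(self.t) or self.t < 0:
            raise ParameterError(f"t must be a nonnegative time, got {self.t!r}")

    @property
    def n_nodes(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class PhysicalConcentrationProfile:
    """A concentration profile in physical units (cm, M, s)."""

    x: np.ndarray  # cm
    A: np.ndarray  # M
    B: np.ndarray  # M
    C: np.ndarray  # M
    t: Union[float, str] = "steady"  # s, or "steady"


def nondimensionalise(dim: DimensionalParameters) -> DimensionlessParameters:
    """Compute the nine dimensionless groups from physical parameters.

    The groups are

    .. code-block:: text

        lambda1 = L^2 k_+1 A* B* / (C* D_C)      lambda2 = L^2 (k_-1 + k_-2) / D_C
        lambda3 = alpha1 L^2 / D_C               lambda4 = alpha2 L^2 / D_C
        lambda5 = L^2 k_-1 C* / (B* D_C)
        delta_A = D_A / D_C                      delta_B = D_B / D_C
        mu_A    = C* / A*                        mu_B    = C* / B*
    """
    d = dim  # validated on construction
    L2_over_DC = d.L**2 / d.D_C
    return DimensionlessParameters(
        lambda1=L2_over_DC * d.k_plus1 * d.A_star * d.B_star / d.C_star,
        lambda2=L2_over_DC * (d.k_minus1 + d.k_minus2),
        lambda3=L2_over_DC * d.alpha1,
        lambda4=L2_over_DC * d.alpha2,
        lambda5=L2_over_DC * d.k_minus1 * d.C_star / d.B_star,
        mu_A=d.C_star / d.A_star,
        mu_B=d.C_star / d.B_star,
        delta_A=d.D_A / d.D_C,
        delta_B=d.D_B / d.D_C,
    )


def redimensionalise(
    profile: ConcentrationProfile, dim: DimensionalParameters
) -> PhysicalConcentrationProfile:
    """Restore physical units to a dimensionless profile.

    Positions are scaled by the tissue half-width ``L``, each concentration
    by its boundary value, and time by the complex diffusion time
    ``L**2 / D_C`` (the ``"steady"`` marker is preserved).
    """
    t = profile.t
    if not isinstance(t, str):
        t = t * dim.L**2 / dim.D_C
    return PhysicalConcentrationProfile(
        x=profile.x * dim.L,
        A=profile.A * dim.A_star,
        B=profile.B * dim.B_star,
        C=profile.C * dim.C_star,
        t=t,
    )


def nondimensionalise_profile(
    phys: PhysicalConcentrationProfile, dim: DimensionalParameters
) -> ConcentrationProfile:
    """Inverse of :func:`redimensionalise` (forward scaling of a profile)."""
    t = phys.t
    if not isinstance(t, str):
        t = t * dim.D_C / dim.L**2
    return ConcentrationProfile(
        x=phys.x / dim.L,
        A=phys.A / dim.A_star,
        B=phys.B / dim.B_star,
        C=phys.C / dim.C_star,
        t=t,
    )
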