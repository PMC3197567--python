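"""Parameter studies: profile sweeps, regime maps and certification runs.

The steady free-chemical profile falls into one of three qualitative
regimes, controlled chiefly by the removal rate ``lambda3`` relative to
the breakdown rate ``lambda2``:

* ``centre_maximum`` — the global maximum of A sits at the tissue centre
  (slow removal; the released chemical accumulates furthest from the
  boundary sink),
* ``interior_maximum`` — a maximum at some 0 < x < 1 with a local
  minimum at the centre (intermediate removal),
* ``monotone_from_boundary`` — A decreases monotonically from the
  boundary inwards (fast removal).

The ``sweep_*`` drivers reproduce the canonical parameter studies over
``lambda2`` (uptake saturation), ``lambda3`` (regime traversal), the
``(lambda2, lambda3)`` surface of the central concentration, the
first-order correction profiles, and full nonlinear solves over the
complex-formation rate ``lambda1`` and the partner-removal rate
``lambda4``.  Swept grids for the first two studies are package choices
(captions of the source figures fix only the held parameters); they are
recorded in the fixture registry (:mod:`tissuetarget.io`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .analytic import (
    central_A0,
    leading_order_profile,
    small_lambda1_profile,
)
from .corrections import first_order_correction
from .params import ConcentrationProfile, DimensionlessParameters, ParameterError
from .solver import SolverConfig, SteadyStateSolution, run_to_steady

__all__ = [
    "RegimeClassification",
    "SweepResult",
    "ComparisonReport",
    "classify_profile",
    "sweep_lambda2",
    "sweep_lambda3",
    "regime_transitions",
    "central_A0_surface",
    "correction_profiles",
    "full_model_sweep",
    "compare_analytic_numeric",
]

#: Relative plateau tolerance used when classifying discrete profiles.
_PLATEAU_RTOL = 1e-9


@dataclass(frozen=True)
class RegimeClassification:
    """Qualitative shape of a steady free-chemical profile."""

    regime: str  # centre_maximum | interior_maximum | monotone_from_boundary
    argmax_x: float
    max_value: float


@dataclass(frozen=True)
class SweepResult:
    """Profiles and classifications along a one-parameter sweep."""

    swept_parameter: str
    values: np.ndarray
    profiles: List[ConcentrationProfile]
    classifications: List[RegimeClassification]

    def __post_init__(self) -> None:
        if not (len(self.values) == len(self.profiles) == len(self.classifications)):
            raise ParameterError("sweep values, profiles and classifications must align")


@dataclass(frozen=True)
class ComparisonReport:
    """Discrepancy between the analytic expansion and the full solver."""

    max_abs: Dict[str, float]
    max_rel: Dict[str, float]
    expansion_warnings: List[str]
    solver: SteadyStateSolution


def classify_profile(profile: ConcentrationProfile) -> RegimeClassification:
    """Classify a steady A-profile into one of the three regimes.

    Discrete profiles need explicit tie-breaking: values within a
    relative ``1e-9`` of the maximum are treated as lying on the maximal
    plateau.  If the centre belongs to the plateau and the boundary does
    not, the profile is a centre maximum; if the plateau reaches the
    boundary node (or the node next to it) — including the degenerate
    constant profile — it is monotone from the boundary; anything else is
    an interior maximum.
    """
    if profile.n_nodes < 101:
        raise ParameterError(
            "classification needs at least 101 nodes to be reliable"
        )
    A = profile.A
    mx = float(np.max(A))
    tol = _PLATEAU_RTOL * max(abs(mx), 1.0)
    on_plateau = A >= mx - tol
    if on_plateau[0] and not np.any(on_plateau[-2:]):
        return RegimeClassification("centre_maximum", 0.0, float(A[0]))
    if np.any(on_plateau[-2:]):
        return RegimeClassification("monotone_from_boundary", 1.0, float(A[-1]))
    idx = int(np.argmax(A))
    return RegimeClassification("interior_maximum", float(profile.x[idx]), mx)


def _analytic_profile(p: DimensionlessParameters, n_points: int) -> ConcentrationProfile:
    x = np.linspace(0.0, 1.0, n_points)
    A0, B0, C0 = leading_order_profile(x, p)
    return ConcentrationProfile(x=x, A=A0, B=B0, C=C0, t="steady")


def _analytic_sweep(
    name: str,
    values: Sequence[float],
    base: DimensionlessParameters,
    n_points: int,
) -> SweepResult:
    values = np.asarray(values, dtype=float)
    profiles = [_analytic_profile(base.with_(**{name: v}), n_points) for v in values]
    return SweepResult(
        swept_parameter=name,
        values=values,
        profiles=profiles,
        classifications=[classify_profile(pr) for pr in profiles],
    )


def sweep_lambda2(
    lambda2_values: Sequence[float] = (1.0, 5.0, 20.0, 100.0, 1000.0),
    n_points: int = 501,
) -> SweepResult:
    """Leading-order profiles for increasing complex-breakdown rate.

    Held parameters: ``lambda3 = 0`` (no removal of the free chemical),
    ``mu_A = 100``, ``delta_A = 1``, ``lambda1 = 0``.  As ``lambda2``
    grows the complex is consumed in an ever-thinner boundary layer while
    the free chemical plateaus towards its supply-limited ceiling
    ``1 + mu_A/delta_A``.
    """
    base = DimensionlessParameters(
        lambda1=0.0, lambda2=1.0, lambda3=0.0, lambda4=0.0, lambda5=0.0,
        mu_A=100.0, mu_B=1.0, delta_A=1.0, delta_B=1.0,
    )
    return _analytic_sweep("lambda2", lambda2_values, base, n_points)


def sweep_lambda3(
    lambda3_values: Optional[Sequence[float]] = None,
    n_points: int = 501,
) -> SweepResult:
    """Leading-order profiles traversing the three regimes in ``lambda3``.

    Held parameters: ``lambda2 = 50``, ``lambda4 = lambda5 = 0``,
    ``mu_A = mu_B = delta_A = delta_B = 1``, ``lambda1 = 0``.  The default
    grid is 200 points log-spaced over [1e-2, 1e2], dense enough to
    resolve both regime transitions.
    """
    if lambda3_values is None:
        lambda3_values = np.logspace(-2.0, 2.0, 200)
    base = DimensionlessParameters(
        lambda1=0.0, lambda2=50.0, lambda3=0.0, lambda4=0.0, lambda5=0.0,
        mu_A=1.0, mu_B=1.0, delta_A=1.0, delta_B=1.0,
    )
    return _analytic_sweep("lambda3", lambda3_values, base, n_points)


def regime_transitions(sweep: SweepResult) -> Dict[str, Tuple[float, float]]:
    """Bracket the parameter values where the regime changes.

    Returns, for each transition observed along the sweep, the last value
    in the old regime and the first in the new one, keyed as
    ``"old->new"``.  Raises if the sweep revisits a regime (re-entrant
    classification would indicate either a too-coarse grid or a bug).
    """
    regimes = [c.regime for c in sweep.classifications]
    seen = [regimes[0]]
    out: Dict[str, Tuple[float, float]] = {}
    for i in range(1, len(regimes)):
        if regimes[i] != regimes[i - 1]:
            if regimes[i] in seen:
                raise ParameterError(
                    f"re-entrant regime {regimes[i]} along the sweep"
                )
            seen.append(regimes[i])
            out[f"{regimes[i - 1]}->{regimes[i]}"] = (
                float(sweep.values[i - 1]),
                float(sweep.values[i]),
            )
    return out


def central_A0_surface(
    lambda2_values: Optional[Sequence[float]] = None,
    lambda3_values: Optional[Sequence[float]] = None,
    mu_A: float = 1.0,
    delta_A: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Central free-chemical concentration over a (lambda2, lambda3) grid.

    Returns ``(lambda2_values, lambda3_values, surface)`` where
    ``surface[i, j]`` is A0(0) at ``lambda2_values[i]``,
    ``lambda3_values[j]``.  With ``mu_A/delta_A = 1`` the surface is
    bounded by 2, approached at large ``lambda2`` with no removal.
    """
    if lambda2_values is None:
        lambda2_values = np.logspace(-1.0, 4.0, 26)
    if lambda3_values is None:
        lambda3_values = np.concatenate(([0.0], np.logspace(-2.0, 2.0, 25)))
    lambda2_values = np.asarray(lambda2_values, dtype=float)
    lambda3_values = np.asarray(lambda3_values, dtype=float)
    surface = np.empty((lambda2_values.size, lambda3_values.size))
    for i, l2 in enumerate(lambda2_values):
        for j, l3 in enumerate(lambda3_values):
            p = DimensionlessParameters(
                lambda1=0.0, lambda2=l2, lambda3=l3, lambda4=0.0, lambda5=0.0,
                mu_A=mu_A, mu_B=1.0, delta_A=delta_A, delta_B=1.0,
            )
            surface[i, j] = central_A0(p)
    return lambda2_values, lambda3_values, surface


def correction_profiles(
    parameter_sets: Dict[str, DimensionlessParameters],
    n_points: int = 201,
) -> Dict[str, Dict[str, np.ndarray]]:
    """First-order correction profiles for named parameter sets.

    For each set, returns a dict with keys ``x``, ``A1``, ``B1``, ``C1``.
    For every set the free-chemical correction is nonpositive and the
    complex correction nonnegative, with the largest magnitude at the
    tissue centre: complex re-formation depletes the free chemical and
    restores the complex, most strongly where the chemical accumulates.
    """
    x = np.linspace(0.0, 1.0, n_points)
    out = {}
    for name, p in parameter_sets.items():
        A1, B1, C1 = first_order_correction(x, p)
        out[name] = {"x": x, "A1": A1, "B1": B1, "C1": C1}
    return out


def full_model_sweep(
    base: DimensionlessParameters,
    swept_parameter: str,
    values: Sequence[float],
    config: Optional[SolverConfig] = None,
) -> SweepResult:
    """Steady solutions of the full nonlinear model along a sweep.

    Each value replaces ``swept_parameter`` in ``base`` and the solver is
    run from the uniform initial state.  Deterministic: repeated calls
    with identical inputs produce identical profiles.
    """
    config = config or SolverConfig()
    values = np.asarray(values, dtype=float)
    profiles = []
    for v in values:
        sol = run_to_steady(base.with_(**{swept_parameter: v}), config)
        profiles.append(sol.profile)
    return SweepResult(
        swept_parameter=swept_parameter,
        values=values,
        profiles=profiles,
        classifications=[classify_profile(pr) for pr in profiles],
    )


def compare_analytic_numeric(
    p: DimensionlessParameters,
    config: Optional[SolverConfig] = None,
) -> ComparisonReport:
    """Compare the two-term expansion with the full nonlinear solve.

    Runs the solver at ``p`` (including its ``lambda1``), evaluates the
    truncated expansion on the same grid, and reports per-species maximum
    absolute and relative discrepancies together with any expansion-
    validity warnings that fired.  For ``lambda1 = 0`` and O(1)
    parameters the discrepancy is pure discretisation error.
    """
    import warnings as _warnings

    config = config or SolverConfig()
    sol = run_to_steady(p, config)
    x = sol.profile.x
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        Aa, Ba, Ca = small_lambda1_profile(x, p)
    messages = [str(w.message) for w in caught]
    max_abs = {}
    max_rel = {}
    for name, num, ana in (
        ("A", sol.profile.A, Aa),
        ("B", sol.profile.B, Ba),
        ("C", sol.profile.C, Ca),
    ):
        diff = np.abs(num - ana)
        max_abs[name] = float(np.max(diff))
        max_rel[name] = float(np.max(diff / np.maximum(np.abs(num), 1e-300)))
    return ComparisonReport(
        max_abs=max_abs, max_rel=max_rel, expansion_warnings=messages, solver=sol
    )
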