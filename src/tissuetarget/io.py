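"""Configuration loading, CSV/JSON output and the named fixture registry.

JSON configurations carry one of two top-level parameter shapes::

    {"dimensional":    {"D_A": ..., "k_plus1": ..., ...}}
    {"dimensionless":  {"lambda1": ..., "mu_A": ..., ...}}

plus an optional ``"solver"`` block with :class:`~tissuetarget.solver.
SolverConfig` fields.  Dimensional inputs are nondimensionalised on load
and the resulting groups are echoed in the run manifest.

Every CSV written by this module gets a JSON manifest sidecar
(``<name>.manifest.json``) recording the package version, a timestamp,
the configuration echo and any convergence diagnostics, so a results
directory is self-describing.

The fixture registry names the parameter sets of the canonical studies
("fig2" .. "fig8"), the dimensional IGF/cartilage order-of-magnitude
estimate ("igf_estimate") and a published counterexample probing the
validity limit of the small-``lambda1`` expansion
("reviewer1_counterexample").
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .experiments import SweepResult
from .params import (
    ConcentrationProfile,
    DimensionalParameters,
    DimensionlessParameters,
    ParameterError,
    nondimensionalise,
)
from .solver import SolverConfig

__all__ = [
    "ConfigError",
    "RunManifest",
    "FigureFixture",
    "load_config",
    "fixture",
    "available_fixtures",
    "write_profile",
    "read_profile",
    "write_sweep",
    "write_surface",
]


class ConfigError(ValueError):
    """A configuration file is malformed; the message lists every problem."""


@dataclass(frozen=True)
class RunManifest:
    """Sidecar metadata written next to every CSV output."""

    config: dict
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    diagnostics: dict = field(default_factory=dict)

    def write(self, csv_path: Union[str, Path]) -> Path:
        path = Path(str(csv_path) + ".manifest.json")
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path


@dataclass(frozen=True)
class FigureFixture:
    """A named study: one parameter set per curve, plus the swept name."""

    name: str
    curves: Dict[str, DimensionlessParameters]
    swept_parameter: Optional[str]
    description: str


def _dataclass_from_dict(cls, data: dict, label: str, errors: List[str]):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        errors.append(f"{label}: unknown keys {sorted(unknown)}")
    clean = {}
    for key, value in data.items():
        if key not in known:
            continue
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            errors.append(f"{label}.{key}: expected a number, got {value!r}")
        else:
            clean[key] = float(value)
    required = {
        f.name
        for f in dataclasses.fields(cls)
        if f.default is dataclasses.MISSING
        and f.default_factory is dataclasses.MISSING  # type: ignore[misc]
    }
    missing = required - set(clean)
    if missing:
        errors.append(f"{label}: missing required keys {sorted(missing)}")
    if errors:
        return None
    if cls is SolverConfig and "max_steps" in clean:
        clean["max_steps"] = int(clean["max_steps"])
    if cls is SolverConfig and "report_every" in clean:
        clean["report_every"] = int(clean["report_every"])
    try:
        return cls(**clean)
    except ParameterError as exc:
        errors.append(f"{label}: {exc}")
        return None


def load_config(
    path: Union[str, Path],
) -> Tuple[DimensionlessParameters, SolverConfig, RunManifest]:
    """Load and validate a JSON configuration.

    Returns the (possibly nondimensionalised) parameter set, a solver
    configuration (defaults applied where the file is silent) and a
    manifest echoing the raw configuration; for dimensional input the
    manifest's diagnostics record the computed dimensionless groups.
    All validation problems are collected and reported in one error.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a JSON object")

    errors: List[str] = []
    known_top = {"dimensional", "dimensionless", "solver"}
    unknown = set(raw) - known_top
    if unknown:
        errors.append(f"unknown top-level keys {sorted(unknown)}")
    has_dim = "dimensional" in raw
    has_nondim = "dimensionless" in raw
    if has_dim == has_nondim:
        errors.append(
            "exactly one of 'dimensional' or 'dimensionless' must be present"
        )

    params = None
    diagnostics: dict = {}
    if has_dim and not has_nondim:
        dim = _dataclass_from_dict(
            DimensionalParameters, raw["dimensional"], "dimensional", errors
        )
        if dim is not None:
            params = nondimensionalise(dim)
            diagnostics["dimensionless_groups"] = dataclasses.asdict(params)
    elif has_nondim and not has_dim:
        params = _dataclass_from_dict(
            DimensionlessParameters, raw["dimensionless"], "dimensionless", errors
        )

    solver = _dataclass_from_dict(SolverConfig, raw.get("solver", {}), "solver", errors)

    if errors or params is None or solver is None:
        raise ConfigError(f"{path}: " + "; ".join(errors))
    manifest = RunManifest(config=raw, diagnostics=diagnostics)
    return params, solver, manifest


# ---------------------------------------------------------------------------
# fixture registry


def _p(l1, l2, l3, l4, l5, muA, muB, dA, dB) -> DimensionlessParameters:
    return DimensionlessParameters(
        lambda1=l1, lambda2=l2, lambda3=l3, lambda4=l4, lambda5=l5,
        mu_A=muA, mu_B=muB, delta_A=dA, delta_B=dB,
    )


def _build_fixtures() -> Dict[str, object]:
    fixtures: Dict[str, object] = {}

    # Breakdown-rate sweep: lambda3 = 0, mu_A = 100, delta_A = 1 held; the
    # swept lambda2 values are a package choice spanning slow to very fast
    # breakdown.
    fixtures["fig2"] = FigureFixture(
        name="fig2",
        curves={
            f"lambda2={v:g}": _p(0, v, 0, 0, 0, 100, 1, 1, 1)
            for v in (1.0, 5.0, 20.0, 100.0, 1000.0)
        },
        swept_parameter="lambda2",
        description="Free chemical and complex for increasing breakdown rate "
        "(lambda3=0, mu_A=100, delta_A=1).",
    )
    # Removal-rate sweep: lambda2 = 50, everything else unity; swept values
    # chosen to land in each of the three regimes (at lambda2 = 50 the
    # centre-maximum regime requires lambda3 below ~0.042).
    fixtures["fig3"] = FigureFixture(
        name="fig3",
        curves={
            f"lambda3={v:g}": _p(0, 50, v, 0, 0, 1, 1, 1, 1)
            for v in (0.01, 0.5, 5.0, 20.0, 100.0)
        },
        swept_parameter="lambda3",
        description="Free-chemical profiles across the three regimes as the "
        "removal rate lambda3 grows (lambda2=50, mu_A=delta_A=1).",
    )
    fixtures["fig4"] = FigureFixture(
        name="fig4",
        curves={"base": _p(0, 1, 0, 0, 0, 1, 1, 1, 1)},
        swept_parameter=None,
        description="Central concentration A0(0) over a (lambda2, lambda3) "
        "grid with mu_A/delta_A = 1.",
    )
    # Correction-term sets.  The printed caption lists lambda4 both per-curve
    # (0.2) and in the held set; the held set is taken as lambda4 = 0.2 with
    # lambda5 = mu_B = delta_A = delta_B = 1.
    fig5_held = dict(l4=0.2, l5=1.0, muB=1.0, dA=1.0, dB=1.0)
    fixtures["fig5"] = FigureFixture(
        name="fig5",
        curves={
            "dashed": _p(0, 5, 0.5, fig5_held["l4"], fig5_held["l5"], 1,
                         fig5_held["muB"], fig5_held["dA"], fig5_held["dB"]),
            "dot-dashed": _p(0, 2, 1.5, fig5_held["l4"], fig5_held["l5"], 1,
                             fig5_held["muB"], fig5_held["dA"], fig5_held["dB"]),
            "solid": _p(0, 1, 0.5, fig5_held["l4"], fig5_held["l5"], 5,
                        fig5_held["muB"], fig5_held["dA"], fig5_held["dB"]),
        },
        swept_parameter=None,
        description="First-order correction terms A1 and C1 for three "
        "parameter sets (lambda4=0.2, lambda5=mu_B=delta_A=delta_B=1).",
    )
    fixtures["fig6"] = FigureFixture(
        name="fig6",
        curves={
            f"lambda1={v:g}": _p(v, 5, 0.5, 1, 1, 1, 1, 1, 1)
            for v in (0.0, 2.0, 20.0)
        },
        swept_parameter="lambda1",
        description="Full-model steady states for increasing complex-"
        "formation rate (lambda2=5, lambda3=0.5, all other groups 1).",
    )
    fixtures["fig7"] = FigureFixture(
        name="fig7",
        curves={
            f"lambda1={v:g}": _p(v, 1, 0.5, 0.5, 12, 10, 0.2, 0.02, 0.1)
            for v in (0.0, 0.01)
        },
        swept_parameter="lambda1",
        description="Full-model steady states with non-O(1) groups "
        "(mu_A/delta_A = 500): a tiny lambda1 visibly shifts A.",
    )
    fixtures["fig8"] = FigureFixture(
        name="fig8",
        curves={
            f"lambda1={v:g}": _p(v, 1, 0.5, 10, 12, 10, 0.2, 0.02, 0.1)
            for v in (0.0, 0.01)
        },
        swept_parameter="lambda1",
        description="As fig7 but with fast partner removal (lambda4=10): "
        "less b to tie up a, hence more free chemical.",
    )
    # Order-of-magnitude IGF/cartilage estimate: boundary concentrations
    # ~1e-11 M (free IGF and binding protein) and ~1e-9 M (complex),
    # L ~ 1 mm, association at 1e5 /M/s, diffusivities ~1e-7 cm^2/s.
    fixtures["igf_estimate"] = DimensionalParameters(
        D_A=1e-7, D_B=1e-7, D_C=1e-7,
        k_plus1=1e5, k_minus1=0.0, k_minus2=0.0,
        alpha1=0.0, alpha2=0.0,
        L=1e-1, A_star=1e-11, B_star=1e-11, C_star=1e-9,
    )
    return fixtures


_FIXTURES: Optional[Dict[str, object]] = None


def _fixtures() -> Dict[str, object]:
    global _FIXTURES
    if _FIXTURES is None:
        _FIXTURES = _build_fixtures()
    return _FIXTURES


def available_fixtures() -> List[str]:
    return sorted(_fixtures()) + ["reviewer1_counterexample"]


def fixture(name: str):
    """Return the named parameter fixture.

    Figure fixtures ("fig2" .. "fig8") return a :class:`FigureFixture`;
    "igf_estimate" a :class:`DimensionalParameters`;
    "reviewer1_counterexample" a :class:`DimensionlessParameters` with
    ``mu_B = 0`` (issued with a :class:`~tissuetarget.params.
    ZeroCouplingWarning`), the published set for which the small-
    ``lambda1`` expansion fails because ``lambda1*mu_A/delta_A`` is large.
    """
    if name == "reviewer1_counterexample":
        # Constructed lazily so the zero-coupling warning fires at the
        # point of use, not at import.
        return _p(0.1, 1, 0.5, 0.1, 12, 10, 0.0, 0.01, 0.1)
    try:
        return _fixtures()[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {available_fixtures()}"
        ) from None


# ---------------------------------------------------------------------------
# CSV output


def write_profile(
    profile: ConcentrationProfile,
    path: Union[str, Path],
    manifest: Optional[RunManifest] = None,
    leading_order_columns: Optional[dict] = None,
) -> Path:
    """Write a profile as CSV (columns x, A, B, C) with a manifest sidecar.

    Values are written in full double precision so a write/read round
    trip is lossless.  ``leading_order_columns`` may carry extra columns
    (e.g. A0/B0/C0 or correction terms) keyed by column name.
    """
    path = Path(path)
    data = {"x": profile.x, "A": profile.A, "B": profile.B, "C": profile.C}
    if leading_order_columns:
        for key, col in leading_order_columns.items():
            data[key] = np.asarray(col, dtype=float)
    frame = pd.DataFrame(data)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.17g")
    (manifest or RunManifest(config={"t": str(profile.t)})).write(path)
    return path


def read_profile(path: Union[str, Path], t: Union[float, str] = "steady") -> ConcentrationProfile:
    """Read a profile CSV written by :func:`write_profile`."""
    # round_trip parsing: the default fast parser loses the last ulp,
    # breaking lossless write/read round trips
    frame = pd.read_csv(path, float_precision="round_trip")
    return ConcentrationProfile(
        x=frame["x"].to_numpy(),
        A=frame["A"].to_numpy(),
        B=frame["B"].to_numpy(),
        C=frame["C"].to_numpy(),
        t=t,
    )


def write_sweep(
    result: SweepResult,
    out_dir: Union[str, Path],
    manifest: Optional[RunManifest] = None,
) -> List[Path]:
    """Write one CSV per sweep value plus a classification summary CSV."""
    if len(result.values) == 0:
        raise ParameterError("refusing to write an empty sweep")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for value, profile in zip(result.values, result.profiles):
        name = f"{result.swept_parameter}={value:g}.csv"
        paths.append(write_profile(profile, out_dir / name, manifest))
    summary = pd.DataFrame(
        {
            result.swept_parameter: result.values,
            "regime": [c.regime for c in result.classifications],
            "argmax_x": [c.argmax_x for c in result.classifications],
            "max_value": [c.max_value for c in result.classifications],
        }
    )
    summary_path = out_dir / "classification.csv"
    summary.to_csv(summary_path, index=False, float_format="%.17g")
    (manifest or RunManifest(config={"swept_parameter": result.swept_parameter})).write(
        summary_path
    )
    paths.append(summary_path)
    return paths


def write_surface(
    lambda2_values: np.ndarray,
    lambda3_values: np.ndarray,
    surface: np.ndarray,
    path: Union[str, Path],
    manifest: Optional[RunManifest] = None,
) -> Path:
    """Write a central-concentration surface in long form.

    Columns: lambda2, lambda3, A0_centre.
    """
    l2, l3 = np.meshgrid(lambda2_values, lambda3_values, indexing="ij")
    frame = pd.DataFrame(
        {
            "lambda2": l2.ravel(),
            "lambda3": l3.ravel(),
            "A0_centre": np.asarray(surface).ravel(),
        }
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.17g")
    (manifest or RunManifest(config={"surface": "A0_centre"})).write(path)
    return path
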