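"""Simulation studies: coefficient sweeps, scenario constraint families,
and scenario selection by trajectory distance.

The two-source specialization (negative, neutral -> positive) is swept
under two controlled designs — conversion proportions fixed while the
transfer coefficients trade off (a2 = 1 - a1), and vice versa — and
under four *scenario rules* linking (a2, b2) to (a1, b1):

    1: a2 = a1,     b2 = b1        (resources and efficiency for both)
    2: a2 = a1,     b2 = 1 - b1    (efficiency for both, strength trades off)
    3: a2 = 1 - a1, b2 = b1        (strength for both, efficiency trades off)
    4: a2 = 1 - a1, b2 = 1 - b1    (both trade off; the surface has a saddle)

Scenario selection compares the target-emotion trajectory under the
estimated (a2, b2) against the trajectory under the scenario-mapped
(a2, b2) = rule(a1_est, b1_est) by Euclidean distance on a time grid.
Absolute distances depend on that grid; only the rank order is a robust
statement.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InvalidInputError
from .model import TransferModelSpec, equilibrate, equilibrium_point

__all__ = [
    "SCENARIO_IDS",
    "ScenarioDistance",
    "apply_scenario",
    "sweep_equilibria",
    "scenario_grid",
    "scenario_distance",
    "scenario_distances",
    "rank_scenarios",
    "DEFAULT_GRID",
]

SCENARIO_IDS = (1, 2, 3, 4)

#: inclusive 0.1 .. 0.9 grid, step 0.1 (81 combinations over two axes)
DEFAULT_GRID = np.round(np.arange(1, 10) * 0.1, 10)


def apply_scenario(scenario: int, a1: float, b1: float) -> tuple[float, float]:
    """Map (a1, b1) to the constrained (a2, b2) of the given scenario."""
    if scenario not in SCENARIO_IDS:
        raise InvalidInputError(f"scenario must be one of {SCENARIO_IDS}, got {scenario}")
    if not (0 < a1 < 1 and 0 < b1 < 1):
        raise DomainError(f"(a1, b1) must lie in (0, 1)^2, got ({a1}, {b1})")
    a2 = a1 if scenario in (1, 2) else 1.0 - a1
    b2 = b1 if scenario in (1, 3) else 1.0 - b1
    return a2, b2


def _require_two_sources(spec: TransferModelSpec) -> None:
    if spec.n != 2:
        raise InvalidInputError(
            f"scenario rules link source 2 to source 1 and need exactly 2 sources, got {spec.n}"
        )


def sweep_equilibria(
    base: TransferModelSpec,
    control: str,
    fixed: float,
    grid: Sequence[float] = DEFAULT_GRID,
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Sweep one coefficient pair while holding the other fixed.

    ``control="a"``: a1 runs over ``grid`` with a2 = 1 - a1 while
    b1 = b2 = ``fixed``. ``control="b"``: b1 runs over ``grid`` with
    b2 = 1 - b1 while a1 = a2 = ``fixed``. Each row reports the
    equilibrium simulated to convergence (scaled-derivative tolerance
    ``tol``) together with the closed-form values and per-emotion
    proportions of the simulated state.
    """
    _require_two_sources(base)
    if control not in ("a", "b"):
        raise InvalidInputError(f"control must be 'a' or 'b', got {control!r}")
    grid = np.asarray(grid, dtype=float)
    if not np.all((grid > 0) & (grid < 1)) or not (0 < fixed < 1):
        raise DomainError("grid values and the fixed coefficient must lie in (0, 1)")
    rows = []
    for v in grid:
        if control == "a":
            a = (v, 1.0 - v)
            b = (fixed, fixed)
        else:
            a = (fixed, fixed)
            b = (v, 1.0 - v)
        spec = base.with_coefficients(a=a, b=b)
        state = equilibrate(spec, tol=tol)
        props = state / state.sum()
        closed = equilibrium_point(spec).values
        row = {"a1": a[0], "a2": a[1], "b1": b[0], "b2": b[1]}
        for j, lab in enumerate(spec.labels):
            row[f"{lab}_value"] = state[j]
            row[f"{lab}_proportion"] = props[j]
            row[f"{lab}_closed_form"] = closed[j]
        rows.append(row)
    return pd.DataFrame(rows)


def scenario_grid(
    scenario: int,
    base: TransferModelSpec,
    grid: Sequence[float] = DEFAULT_GRID,
    simulated: bool = False,
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Target-emotion equilibrium over the (a1, b1) grid under one scenario.

    By default the closed form is used (fast and deterministic); pass
    ``simulated=True`` to integrate each grid point to convergence
    instead, reproducing the small finite-horizon deviations of a
    simulated sweep.
    """
    _require_two_sources(base)
    grid = np.asarray(grid, dtype=float)
    rows = []
    for a1 in grid:
        for b1 in grid:
            a2, b2 = apply_scenario(scenario, float(a1), float(b1))
            spec = base.with_coefficients(a=(a1, a2), b=(b1, b2))
            if simulated:
                y_star = float(equilibrate(spec, tol=tol)[-1])
            else:
                y_star = equilibrium_point(spec).target_value
            rows.append({"a1": float(a1), "b1": float(b1), "a2": a2, "b2": b2,
                         "y_star": y_star})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScenarioDistance:
    """Distance between target trajectories with and without a scenario rule."""

    scenario: int
    euclidean: float
    normalized: float | None = None


def scenario_distance(
    spec: TransferModelSpec,
    scenario: int,
    time_grid: Sequence[float],
    baseline: str = "estimated",
) -> ScenarioDistance:
    """Euclidean distance between two target-emotion trajectories.

    One trajectory uses the spec as estimated; the other replaces
    (a2, b2) with the scenario-mapped pair rule(a1, b1). With
    ``baseline="no-transfer"`` the reference trajectory instead shuts
    transfer off entirely (all a_i -> 0), an alternative reading of the
    unconstrained system.
    """
    _require_two_sources(spec)
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid.size == 0:
        raise InvalidInputError("time grid must be non-empty")
    if baseline not in ("estimated", "no-transfer"):
        raise InvalidInputError(f"baseline must be 'estimated' or 'no-transfer', got {baseline!r}")
    a1, b1 = spec.sources[0].a, spec.sources[0].b
    a2, b2 = apply_scenario(scenario, a1, b1)
    mapped = TransferModelSpec(
        sources=(spec.sources[0], replace(spec.sources[1], a=a2, b=b2)),
        target=spec.target,
    )
    if baseline == "estimated":
        ref = spec
    else:
        eps = 1e-12  # coefficients live in the open interval; 0 is a limit
        ref = spec.with_coefficients(a=(eps, eps), b=(b1, spec.sources[1].b))
    y_ref = _sample_target(ref, time_grid)
    y_map = _sample_target(mapped, time_grid)
    return ScenarioDistance(scenario=scenario,
                            euclidean=float(np.linalg.norm(y_ref - y_map)))


def _sample_target(spec: TransferModelSpec, time_grid: np.ndarray) -> np.ndarray:
    """Target-emotion trajectory sampled on an arbitrary increasing grid."""
    if time_grid.size > 1 and not np.all(np.diff(time_grid) > 0):
        raise InvalidInputError("time grid must be strictly increasing")
    from .model import _rhs_unchecked, _solve  # shared integrator internals

    r, K, a, b = spec.coefficient_arrays()
    rt, Kt = spec.target.r, spec.target.K
    fun = lambda t, s: _rhs_unchecked(s, r, K, a, b, rt, Kt)
    if time_grid[-1] == 0:
        return np.array([spec.target.y0])
    sol = _solve(fun, spec.initial_state, horizon=float(time_grid[-1]),
                 t_eval=time_grid, rtol=1e-10, atol=1e-12)
    return sol.y[-1, :]


def scenario_distances(
    spec: TransferModelSpec,
    time_grid: Sequence[float],
    scenarios: Sequence[int] = SCENARIO_IDS,
    baseline: str = "estimated",
) -> list[ScenarioDistance]:
    """Distances for several scenarios, with normalized shares filled in."""
    if len(scenarios) < 1:
        raise InvalidInputError("at least one scenario id is required")
    raw = [scenario_distance(spec, s, time_grid, baseline=baseline) for s in scenarios]
    total = sum(d.euclidean for d in raw)
    return [replace(d, normalized=(d.euclidean / total if total > 0 else 1.0 / len(raw)))
            for d in raw]


def rank_scenarios(distances: Sequence[ScenarioDistance]) -> pd.DataFrame:
    """Ascending by Euclidean distance; ties break on scenario id."""
    if len(distances) < 2:
        raise InvalidInputError("need at least 2 scenario distances to rank")
    total = sum(d.euclidean for d in distances)
    rows = sorted(distances, key=lambda d: (d.euclidean, d.scenario))
    return pd.DataFrame(
        {
            "scenario": [d.scenario for d in rows],
            "euclidean": [d.euclidean for d in rows],
            "normalized": [
                d.euclidean / total if total > 0 else 1.0 / len(rows) for d in rows
            ],
        }
    )
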