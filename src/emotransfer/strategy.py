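"""Guidance-strategy optimization on the fitted equilibrium surface.

The target-emotion equilibrium over a scenario's (a1, b1) grid is
fitted with a full bivariate quadratic by ordinary least squares,

    f(a1, b1) = c_a2 a1^2 + c_ab a1 b1 + c_b2 b1^2 + c_a a1 + c_b b1 + c_0,

and the guidance strategy is improved by fixed-step gradient ascent

    a1 <- a1 + gamma * df/da1,   b1 <- b1 + gamma * df/db1,

stopping when the next iterate would leave the admissible box, when the
update norm falls below a convergence tolerance, or at the iteration
cap. Each iterate carries the relative-change columns of a policy-path
table and maps back to a five-tuple strategy (y, a1, a2, b1, b2)
through the active scenario rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateGridError, DomainError, InvalidInputError
from .model import TransferModelSpec
from .scenarios import DEFAULT_GRID, apply_scenario, scenario_grid

__all__ = [
    "QuadraticSurface",
    "PolicyPath",
    "GuidanceResult",
    "fit_quadratic_surface",
    "surface_gradient",
    "gradient_ascent",
    "optimize_guidance",
    "DEFAULT_BOUNDS",
]

DEFAULT_BOUNDS: tuple[tuple[float, float], tuple[float, float]] = ((0.01, 0.99), (0.01, 0.99))


@dataclass(frozen=True)
class QuadraticSurface:
    """Bivariate quadratic response surface over (a1, b1)."""

    c_a2: float
    c_ab: float
    c_b2: float
    c_a: float
    c_b: float
    c_0: float
    domain: tuple[tuple[float, float], tuple[float, float]] = ((0.1, 0.9), (0.1, 0.9))
    fit_rms: float = 0.0

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.c_a2, self.c_ab, self.c_b2, self.c_a, self.c_b, self.c_0])

    def __call__(self, a1, b1):
        a1 = np.asarray(a1, dtype=float)
        b1 = np.asarray(b1, dtype=float)
        val = (self.c_a2 * a1**2 + self.c_ab * a1 * b1 + self.c_b2 * b1**2
               + self.c_a * a1 + self.c_b * b1 + self.c_0)
        return float(val) if val.ndim == 0 else val

    def gradient(self, a1: float, b1: float) -> tuple[float, float]:
        return (
            2.0 * self.c_a2 * a1 + self.c_ab * b1 + self.c_a,
            2.0 * self.c_b2 * b1 + self.c_ab * a1 + self.c_b,
        )

    def to_dict(self) -> dict:
        return {
            "coefficients": {
                "a1^2": self.c_a2, "a1*b1": self.c_ab, "b1^2": self.c_b2,
                "a1": self.c_a, "b1": self.c_b, "1": self.c_0,
            },
            "domain": {"a1": list(self.domain[0]), "b1": list(self.domain[1])},
            "fit_rms": self.fit_rms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticSurface":
        c = d["coefficients"]
        dom = d.get("domain", {"a1": [0.1, 0.9], "b1": [0.1, 0.9]})
        return cls(c_a2=c["a1^2"], c_ab=c["a1*b1"], c_b2=c["b1^2"],
                   c_a=c["a1"], c_b=c["b1"], c_0=c["1"],
                   domain=(tuple(dom["a1"]), tuple(dom["b1"])),
                   fit_rms=d.get("fit_rms", 0.0))


def fit_quadratic_surface(points: pd.DataFrame | np.ndarray) -> QuadraticSurface:
    """Ordinary least squares over the six quadratic monomials.

    ``points`` is either an (N, 3) array of (a1, b1, y) rows or a frame
    with columns a1, b1 and y_star (or y). Needs at least 6 distinct,
    non-degenerate points.
    """
    if isinstance(points, pd.DataFrame):
        ycol = "y_star" if "y_star" in points.columns else "y"
        arr = points[["a1", "b1", ycol]].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise InvalidInputError(f"points must be (N, 3) rows of (a1, b1, y), got {arr.shape}")
    a1, b1, y = arr.T
    if np.unique(arr[:, :2], axis=0).shape[0] < 6:
        raise DegenerateGridError("need at least 6 distinct (a1, b1) points to fit a quadratic")
    X = np.column_stack([a1**2, a1 * b1, b1**2, a1, b1, np.ones_like(a1)])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 6:
        raise DegenerateGridError(
            f"quadratic design is rank deficient (rank {rank} < 6); the grid is degenerate"
        )
    resid = y - X @ coef
    return QuadraticSurface(
        c_a2=float(coef[0]), c_ab=float(coef[1]), c_b2=float(coef[2]),
        c_a=float(coef[3]), c_b=float(coef[4]), c_0=float(coef[5]),
        domain=((float(a1.min()), float(a1.max())), (float(b1.min()), float(b1.max()))),
        fit_rms=float(np.sqrt(np.mean(resid**2))),
    )


def surface_gradient(surface: QuadraticSurface, a1: float, b1: float) -> tuple[float, float]:
    """(df/da1, df/db1) of the fitted surface at a point."""
    return surface.gradient(a1, b1)


@dataclass(frozen=True)
class PolicyPath:
    """Gradient-ascent iterate sequence with relative-change columns."""

    iterates: pd.DataFrame  # columns n, a1, b1, y_hat, rel_da1, rel_db1, rel_dy
    gamma: float
    termination: str  # "bounds" | "converged" | "max_iter"

    def __len__(self) -> int:
        return len(self.iterates)


def gradient_ascent(
    surface: QuadraticSurface,
    start: tuple[float, float],
    gamma: float = 1e-7,
    bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_BOUNDS,
    max_iter: int = 100,
    tol: float = 1e-12,
) -> PolicyPath:
    """Fixed-step gradient ascent from ``start`` on the fitted surface.

    The path stops *before* an iterate would leave ``bounds``
    (termination "bounds"), when both updates fall below ``tol``
    ("converged"), or after ``max_iter`` steps ("max_iter"). The n = 0
    row has zero relative changes by definition.
    """
    if gamma <= 0:
        raise DomainError(f"step length gamma must be > 0, got {gamma}")
    (a_lo, a_hi), (b_lo, b_hi) = bounds
    a1, b1 = float(start[0]), float(start[1])
    if not (a_lo <= a1 <= a_hi and b_lo <= b1 <= b_hi):
        raise DomainError(f"start ({a1}, {b1}) lies outside bounds {bounds}")
    rows = [(0, a1, b1, surface(a1, b1), 0.0, 0.0, 0.0)]
    termination = "max_iter"
    for n in range(1, max_iter + 1):
        ga, gb = surface.gradient(a1, b1)
        da, db = gamma * ga, gamma * gb
        if max(abs(da), abs(db)) < tol:
            termination = "converged"
            break
        na, nb = a1 + da, b1 + db
        if not (a_lo <= na <= a_hi and b_lo <= nb <= b_hi):
            termination = "bounds"
            break
        y_prev = rows[-1][3]
        y_new = surface(na, nb)
        rel = lambda delta, prev: delta / prev if prev != 0 else np.nan
        rows.append((n, na, nb, y_new, rel(da, a1), rel(db, b1),
                     rel(y_new - y_prev, y_prev)))
        a1, b1 = na, nb
    iterates = pd.DataFrame(
        rows, columns=["n", "a1", "b1", "y_hat", "rel_da1", "rel_db1", "rel_dy"]
    )
    return PolicyPath(iterates=iterates, gamma=gamma, termination=termination)


@dataclass(frozen=True)
class GuidanceResult:
    """Surface, ascent path and the per-iterate five-tuple strategies."""

    scenario: int
    surface: QuadraticSurface
    path: PolicyPath
    strategies: pd.DataFrame  # columns n, y_hat, a1, a2, b1, b2


def optimize_guidance(
    spec: TransferModelSpec,
    scenario: int,
    gamma: float = 1e-7,
    start: tuple[float, float] | None = None,
    grid: Sequence[float] = DEFAULT_GRID,
    bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_BOUNDS,
    max_iter: int = 100,
    simulated: bool = False,
) -> GuidanceResult:
    """Grid -> surface -> ascent, starting from the spec's (a1, b1).

    ``spec`` supplies the non-coefficient parameters (and, when
    ``start`` is omitted, the estimated (a1, b1) of its first source).
    The surface is fitted on the scenario's 81-point equilibrium grid
    (closed form by default; ``simulated=True`` integrates each point).
    """
    if start is None:
        if spec.sources[0].a is None or spec.sources[0].b is None:
            raise InvalidInputError(
                "start omitted and the spec's first source has no (a, b) to start from"
            )
        start = (spec.sources[0].a, spec.sources[0].b)
    if not (0 < start[0] < 1 and 0 < start[1] < 1):
        raise DomainError(f"start must lie in (0, 1)^2, got {start}")
    points = scenario_grid(scenario, spec, grid=grid, simulated=simulated)
    surface = fit_quadratic_surface(points)
    path = gradient_ascent(surface, start, gamma=gamma, bounds=bounds, max_iter=max_iter)
    mapped = [apply_scenario(scenario, a, b)
              for a, b in zip(path.iterates["a1"], path.iterates["b1"])]
    strategies = pd.DataFrame({
        "n": path.iterates["n"],
        "y_hat": path.iterates["y_hat"],
        "a1": path.iterates["a1"],
        "a2": [m[0] for m in mapped],
        "b1": path.iterates["b1"],
        "b2": [m[1] for m in mapped],
    })
    return GuidanceResult(scenario=scenario, surface=surface, path=path,
                          strategies=strategies)
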