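"""Coupled-logistic transfer model of online collective emotions.

The model couples ``n`` *source* emotions to one *target* emotion. Each
source ``i`` grows logistically towards its capacity ``K_i`` while a
conversion proportion ``b_i`` of its information is diverted out of it;
a transfer coefficient ``a_i`` controls how much of the diverted amount
actually arrives at the target::

    dx_i/dt = r_i x_i (1 - x_i/K_i - b_i x_i/K_i)
    dy/dt   = r y (1 - y/K + sum_i a_i b_i x_i / K_i)

All amounts are cumulative information counts and therefore strictly
positive; ``a_i`` and ``b_i`` are proportions in the open interval
(0, 1). The system has a unique non-zero fixed point with source
coordinates ``K_i / (1 + b_i)`` and target coordinate
``K (1 + sum_i a_i b_i / (1 + b_i))``: diverting a share ``b_i``
compresses the source's effective capacity, while the target's capacity
is inflated by what it receives.

Time is measured in sampling intervals (one unit = one observation
interval); all rates are per interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import DomainError, InvalidInputError, NumericalError

__all__ = [
    "SourceEmotionSpec",
    "TargetEmotionSpec",
    "TransferModelSpec",
    "Trajectory",
    "EquilibriumPoint",
    "transfer_rhs",
    "equilibrium_point",
    "integrate",
    "integrate_original",
    "equilibrate",
    "proportion_series",
]


@dataclass(frozen=True)
class SourceEmotionSpec:
    """One source emotion: logistic growth plus outward transfer.

    ``a`` (transfer coefficient, guiding efficiency) and ``b``
    (conversion proportion, guiding strength) may be ``None`` for a
    *base* spec whose coefficients are filled in later by a sweep or a
    scenario. ``unchecked=True`` relaxes the open-interval constraint on
    ``a``/``b`` for exploratory use only.
    """

    label: str
    x0: float
    r: float
    K: float
    a: float | None = None
    b: float | None = None
    unchecked: bool = field(default=False, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not (self.r > 0):
            raise DomainError(f"source {self.label!r}: growth rate r must be > 0, got {self.r}")
        if not (self.K > 0):
            raise DomainError(f"source {self.label!r}: capacity K must be > 0, got {self.K}")
        if not (0 < self.x0 < self.K):
            raise DomainError(
                f"source {self.label!r}: initial value x0 must satisfy 0 < x0 < K, "
                f"got x0={self.x0}, K={self.K}"
            )
        if not self.unchecked:
            for name, v in (("a", self.a), ("b", self.b)):
                if v is not None and not (0 < v < 1):
                    raise DomainError(
                        f"source {self.label!r}: {name} must lie in the open interval (0, 1), got {v}"
                    )


@dataclass(frozen=True)
class TargetEmotionSpec:
    """The target emotion receiving transferred information."""

    label: str
    y0: float
    r: float
    K: float

    def __post_init__(self) -> None:
        if not (self.r > 0):
            raise DomainError(f"target {self.label!r}: growth rate r must be > 0, got {self.r}")
        if not (self.K > 0):
            raise DomainError(f"target {self.label!r}: capacity K must be > 0, got {self.K}")
        if not (0 < self.y0 < self.K):
            raise DomainError(
                f"target {self.label!r}: initial value y0 must satisfy 0 < y0 < K, "
                f"got y0={self.y0}, K={self.K}"
            )


@dataclass(frozen=True)
class TransferModelSpec:
    """Full parameterization of the n-source / 1-target transfer system."""

    sources: tuple[SourceEmotionSpec, ...]
    target: TargetEmotionSpec

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", tuple(self.sources))
        if len(self.sources) < 1:
            raise InvalidInputError("at least one source emotion is required")
        labels = self.labels
        if len(set(labels)) != len(labels):
            raise InvalidInputError(f"emotion labels must be unique, got {labels}")

    @property
    def n(self) -> int:
        return len(self.sources)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.sources) + (self.target.label,)

    @property
    def initial_state(self) -> np.ndarray:
        return np.array([s.x0 for s in self.sources] + [self.target.y0], dtype=float)

    @property
    def has_coefficients(self) -> bool:
        return all(s.a is not None and s.b is not None for s in self.sources)

    def coefficient_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Vectors (r_i, K_i, a_i, b_i); raises if any a/b is unset."""
        if not self.has_coefficients:
            missing = [s.label for s in self.sources if s.a is None or s.b is None]
            raise InvalidInputError(
                f"transfer coefficients (a, b) are unset for sources {missing}; "
                "use with_coefficients() to supply them"
            )
        r = np.array([s.r for s in self.sources])
        K = np.array([s.K for s in self.sources])
        a = np.array([s.a for s in self.sources])
        b = np.array([s.b for s in self.sources])
        return r, K, a, b

    def with_coefficients(
        self, a: Sequence[float] | float, b: Sequence[float] | float
    ) -> "TransferModelSpec":
        """Return a copy with transfer coefficients / conversion proportions set."""
        a_arr = np.broadcast_to(np.asarray(a, dtype=float), (self.n,))
        b_arr = np.broadcast_to(np.asarray(b, dtype=float), (self.n,))
        sources = tuple(
            replace(s, a=float(ai), b=float(bi))
            for s, ai, bi in zip(self.sources, a_arr, b_arr)
        )
        return TransferModelSpec(sources=sources, target=self.target)


@dataclass(frozen=True)
class Trajectory:
    """Time grid with per-emotion information amounts (columns follow labels)."""

    times: np.ndarray
    amounts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        amounts = np.atleast_2d(np.asarray(self.amounts, dtype=float))
        if amounts.shape[0] != times.shape[0]:
            raise InvalidInputError(
                f"times ({times.shape[0]}) and amounts ({amounts.shape[0]} rows) disagree"
            )
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise InvalidInputError("trajectory times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "amounts", amounts)
        object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return self.times.shape[0]

    @property
    def terminal(self) -> np.ndarray:
        return self.amounts[-1]

    def proportions(self) -> np.ndarray:
        return proportion_series(self)

    def to_frame(self, shares: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(self.amounts, columns=list(self.labels))
        df.insert(0, "time", self.times)
        if shares:
            props = self.proportions()
            for j, lab in enumerate(self.labels):
                df[f"{lab}_share"] = props[:, j]
        return df


@dataclass(frozen=True)
class EquilibriumPoint:
    """The unique non-zero fixed point of the transfer system."""

    source_values: np.ndarray
    target_value: float
    labels: tuple[str, ...]

    @property
    def values(self) -> np.ndarray:
        return np.append(self.source_values, self.target_value)

    @property
    def proportions(self) -> np.ndarray:
        v = self.values
        return v / v.sum()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"emotion": list(self.labels), "value": self.values, "proportion": self.proportions}
        )


def _rhs_unchecked(state: np.ndarray, r: np.ndarray, K: np.ndarray,
                   a: np.ndarray, b: np.ndarray, rt: float, Kt: float) -> np.ndarray:
    x = state[:-1]
    y = state[-1]
    dx = r * x * (1.0 - x / K - b * x / K)
    dy = rt * y * (1.0 - y / Kt + np.dot(a * b, x / K))
    return np.append(dx, dy)


def transfer_rhs(state: Sequence[float], spec: TransferModelSpec) -> np.ndarray:
    """Right-hand side of the transfer system at ``state`` = (x_1..x_n, y)."""
    state = np.asarray(state, dtype=float)
    if state.shape != (spec.n + 1,):
        raise InvalidInputError(
            f"state must have length n+1 = {spec.n + 1}, got shape {state.shape}"
        )
    if not np.all(np.isfinite(state)) or not np.all(state > 0):
        raise InvalidInputError("state components must be finite and strictly positive")
    r, K, a, b = spec.coefficient_arrays()
    return _rhs_unchecked(state, r, K, a, b, spec.target.r, spec.target.K)


def equilibrium_point(spec: TransferModelSpec) -> EquilibriumPoint:
    """Closed-form non-zero fixed point.

    Source coordinates ``K_i/(1+b_i)``; target coordinate
    ``K (1 + sum_i a_i b_i/(1+b_i))``.
    """
    _, K, a, b = spec.coefficient_arrays()
    x_star = K / (1.0 + b)
    y_star = spec.target.K * (1.0 + np.sum(a * b / (1.0 + b)))
    return EquilibriumPoint(source_values=x_star, target_value=float(y_star), labels=spec.labels)


def _solve(fun, y0: np.ndarray, horizon: float, t_eval: np.ndarray | None,
           rtol: float, atol: float, events=None):
    sol = solve_ivp(fun, (0.0, horizon), y0, method="RK45", t_eval=t_eval,
                    rtol=rtol, atol=atol, events=events, dense_output=False)
    if not sol.success:
        raise NumericalError(f"integration failed at t={sol.t[-1]:.6g}: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        bad = np.where(~np.all(np.isfinite(sol.y), axis=0))[0][0]
        raise NumericalError(f"non-finite state encountered at t={sol.t[bad]:.6g}")
    return sol


def integrate(
    spec: TransferModelSpec,
    horizon: float,
    step: float = 1.0,
    method: str = "rk45",
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the transfer system over [0, horizon], sampled every ``step``.

    ``method="rk45"`` uses adaptive Runge-Kutta (default relative
    tolerance 1e-10); ``method="euler"`` takes fixed explicit Euler
    steps of size ``step``, which for ``step=1`` coincides with the
    unit-interval difference recursion used by the estimator.
    """
    if horizon < 0:
        raise InvalidInputError(f"horizon must be >= 0, got {horizon}")
    if step <= 0:
        raise InvalidInputError(f"step must be > 0, got {step}")
    y0 = spec.initial_state
    transfer_rhs(y0, spec)  # validates state and coefficients
    r, K, a, b = spec.coefficient_arrays()
    rt, Kt = spec.target.r, spec.target.K

    n_steps = int(round(horizon / step))
    times = np.linspace(0.0, n_steps * step, n_steps + 1)
    if horizon == 0 or n_steps == 0:
        return Trajectory(times=np.array([0.0]), amounts=y0[None, :], labels=spec.labels)

    if method == "euler":
        states = np.empty((n_steps + 1, spec.n + 1))
        states[0] = y0
        for k in range(n_steps):
            states[k + 1] = states[k] + step * _rhs_unchecked(states[k], r, K, a, b, rt, Kt)
            if not np.all(np.isfinite(states[k + 1])) or np.any(states[k + 1] <= 0):
                raise NumericalError(
                    f"explicit Euler step produced a non-positive or non-finite state "
                    f"at t={times[k + 1]:.6g}; reduce the step size"
                )
        return Trajectory(times=times, amounts=states, labels=spec.labels)
    if method != "rk45":
        raise InvalidInputError(f"unknown method {method!r}; expected 'rk45' or 'euler'")

    fun = lambda t, s: _rhs_unchecked(s, r, K, a, b, rt, Kt)
    sol = _solve(fun, y0, horizon=times[-1], t_eval=times, rtol=rtol, atol=atol)
    return Trajectory(times=sol.t, amounts=sol.y.T, labels=spec.labels)


def integrate_original(
    x0: float,
    r: float,
    K: float,
    horizon: float,
    step: float = 1.0,
    label: str = "x",
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> Trajectory:
    """Plain logistic baseline dx/dt = r x (1 - x/K), no transfer terms."""
    if not (r > 0 and K > 0 and 0 < x0 <= K):
        raise DomainError(f"require r > 0, K > 0, 0 < x0 <= K; got r={r}, K={K}, x0={x0}")
    if horizon < 0:
        raise InvalidInputError(f"horizon must be >= 0, got {horizon}")
    if step <= 0:
        raise InvalidInputError(f"step must be > 0, got {step}")
    n_steps = int(round(horizon / step))
    times = np.linspace(0.0, n_steps * step, n_steps + 1)
    if n_steps == 0:
        return Trajectory(times=np.array([0.0]), amounts=np.array([[x0]]), labels=(label,))
    sol = _solve(lambda t, s: r * s * (1.0 - s / K), np.array([x0], dtype=float),
                 horizon=times[-1], t_eval=times, rtol=rtol, atol=atol)
    return Trajectory(times=sol.t, amounts=sol.y.T, labels=(label,))


def equilibrate(
    spec: TransferModelSpec,
    tol: float = 1e-10,
    max_horizon: float = 2000.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Integrate until the maximum scaled derivative drops below ``tol``.

    Returns the terminal state. The scale is the largest state
    component, so ``tol`` bounds the relative residual motion. Raises
    :class:`NumericalError` if the criterion is not met by
    ``max_horizon``.
    """
    y0 = spec.initial_state
    transfer_rhs(y0, spec)
    r, K, a, b = spec.coefficient_arrays()
    rt, Kt = spec.target.r, spec.target.K
    fun = lambda t, s: _rhs_unchecked(s, r, K, a, b, rt, Kt)

    def settled(t, s):
        return np.max(np.abs(fun(t, s))) / max(np.max(s), 1.0) - tol

    settled.terminal = True
    settled.direction = -1
    sol = _solve(fun, y0, horizon=max_horizon, t_eval=None, rtol=rtol, atol=atol,
                 events=settled)
    terminal = sol.y[:, -1]
    # the event root is located to finite precision; allow half a tolerance of slack
    if settled(sol.t[-1], terminal) > 0.5 * tol:
        raise NumericalError(
            f"system did not settle below scaled-derivative tolerance {tol:g} "
            f"within horizon {max_horizon:g} (reached t={sol.t[-1]:.6g})"
        )
    return terminal


def proportion_series(traj: Trajectory) -> np.ndarray:
    """Per-time shares of each emotion; every row sums to one."""
    if len(traj) == 0:
        raise InvalidInputError("trajectory is empty")
    totals = traj.amounts.sum(axis=1, keepdims=True)
    return traj.amounts / totals
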