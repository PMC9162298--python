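"""Parameter identification from cumulative multi-emotion time series.

The continuous system is linearized at unit sampling steps into a
difference-equation form and fitted by multiple linear regression with
no intercept:

    dX(k) = r x - (r (1 + b) / K) x^2                     (each source)
    dY(k) = r y - (r / K) y^2 + r sum_i (a_i b_i / K_i) x_i y   (target)

where dX(k) = x(k) - x(k-1) and every regressor is evaluated at the
*previous* sample x(k-1) (forward-Euler alignment, the same recursion
the synthetic "difference" generator uses, so noise-free recursion data
is recovered to machine precision).

Identifiability: the source regression identifies only ``r`` and the
*effective capacity* ``kappa = K / (1 + b)``; the target regression
identifies ``r``, ``K`` and the composites ``psi_i = a_i b_i / K_i``.
Splitting kappa into (K, b) and psi into a requires one extra anchor
per source — a known ``K_i``, a known ``b_i``, or a pre-guidance window
of the series on which a plain logistic fit supplies ``K_i``. The
estimator never invents these silently: :func:`resolve_parameters`
demands explicit anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    CollinearityError,
    DomainError,
    InsufficientDataError,
    InvalidInputError,
)
from .model import (
    SourceEmotionSpec,
    TargetEmotionSpec,
    Trajectory,
    TransferModelSpec,
    integrate,
)

__all__ = [
    "ObservedSeries",
    "RegressionDiagnostics",
    "SourceFit",
    "TargetFit",
    "Anchor",
    "ResolvedParameters",
    "FitResult",
    "difference_series",
    "fit_source_equation",
    "fit_target_equation",
    "regression_diagnostics",
    "resolve_parameters",
    "fit_pipeline",
]

_COND_LIMIT = 1e12


@dataclass(frozen=True)
class ObservedSeries:
    """Cumulative information amounts per emotion on integer sampling indices."""

    times: np.ndarray
    values: np.ndarray
    labels: tuple[str, ...]
    cumulative: bool = True

    def __post_init__(self) -> None:
        times = np.asarray(self.times)
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        labels = tuple(self.labels)
        if values.shape != (times.shape[0], len(labels)):
            raise InvalidInputError(
                f"values shape {values.shape} does not match "
                f"{times.shape[0]} times x {len(labels)} labels"
            )
        if not np.all(np.isfinite(values)) or not np.all(values > 0):
            raise InvalidInputError("observed values must be finite and strictly positive")
        if self.cumulative:
            diffs = np.diff(values, axis=0)
            bad = np.argwhere(diffs < 0)
            if bad.size:
                k, j = bad[0]
                raise InvalidInputError(
                    f"cumulative series must be non-decreasing: column "
                    f"{labels[j]!r} decreases at index {k + 1}"
                )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return self.times.shape[0]

    def column(self, label: str) -> np.ndarray:
        try:
            j = self.labels.index(label)
        except ValueError:
            raise InvalidInputError(
                f"unknown emotion label {label!r}; available: {self.labels}"
            ) from None
        return self.values[:, j]

    def window(self, start: int, stop: int) -> "ObservedSeries":
        return ObservedSeries(self.times[start:stop], self.values[start:stop],
                              self.labels, self.cumulative)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.labels))
        df.insert(0, "time", self.times)
        return df


@dataclass(frozen=True)
class RegressionDiagnostics:
    """No-intercept regression diagnostics.

    ``r_squared`` is the uncentered coefficient of determination
    (1 - SS_res / sum y^2, appropriate for a through-the-origin model);
    ``vif`` comes from uncentered no-intercept auxiliary regressions of
    each regressor on the others; ``f_value`` is the overall F for the
    no-intercept model, (sum fitted^2 / p) / (SS_res / (m - p)). These
    conventions are recorded in ``conventions``.
    """

    r_squared: float
    vif: dict[str, float]
    f_value: float
    residuals: np.ndarray
    conventions: dict[str, str] = field(default_factory=dict)


def _diagnostics(X: np.ndarray, y: np.ndarray, coef: np.ndarray,
                 names: Sequence[str]) -> RegressionDiagnostics:
    fitted = X @ coef
    resid = y - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(y @ y)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    m, p = X.shape
    if m > p and ss_res > 0:
        f_value = (float(fitted @ fitted) / p) / (ss_res / (m - p))
    else:
        f_value = np.inf
    vif: dict[str, float] = {}
    for j, name in enumerate(names):
        if p == 1:
            vif[name] = 1.0
            continue
        others = np.delete(X, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        res_j = X[:, j] - others @ beta
        ssj = float(X[:, j] @ X[:, j])
        r2_j = 1.0 - float(res_j @ res_j) / ssj if ssj > 0 else 0.0
        vif[name] = float(1.0 / (1.0 - r2_j)) if r2_j < 1.0 else np.inf
    return RegressionDiagnostics(
        r_squared=r2,
        vif=vif,
        f_value=f_value,
        residuals=resid,
        conventions={
            "r_squared": "uncentered (no-intercept model)",
            "vif": "uncentered auxiliary no-intercept regressions",
            "f_value": "no-intercept overall F: (ESS/p)/(SS_res/(m-p)), ESS = sum of squared fitted values",
        },
    )


@dataclass(frozen=True)
class SourceFit:
    """Fit of one source difference equation dX on {x, x^2}."""

    label: str
    r_hat: float
    kappa_hat: float  # effective capacity K/(1+b)
    coefficients: np.ndarray
    regressor_names: tuple[str, ...]
    design: np.ndarray
    response: np.ndarray
    diagnostics: RegressionDiagnostics


@dataclass(frozen=True)
class TargetFit:
    """Fit of the target difference equation dY on {y, y^2, x_i*y}."""

    label: str
    source_labels: tuple[str, ...]
    r_hat: float
    K_hat: float
    psi_hat: dict[str, float]  # composites a_i b_i / K_i
    coefficients: np.ndarray
    regressor_names: tuple[str, ...]
    design: np.ndarray
    response: np.ndarray
    diagnostics: RegressionDiagnostics


def difference_series(series: ObservedSeries, emotion: str) -> np.ndarray:
    """First differences x(k) - x(k-1), aligned to k = 1..m."""
    if len(series) < 2:
        raise InsufficientDataError(
            f"need at least 2 time points to difference, got {len(series)}"
        )
    return np.diff(series.column(emotion))


def _check_design(X: np.ndarray, names: Sequence[str]) -> None:
    distinct = np.unique(X, axis=0).shape[0]
    if distinct < X.shape[1]:
        raise InsufficientDataError(
            f"only {distinct} distinct design rows for {X.shape[1]} regressors "
            f"({', '.join(names)}): insufficient variation"
        )
    cond = np.linalg.cond(X)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise CollinearityError(
            f"design matrix with regressors ({', '.join(names)}) is numerically "
            f"singular: condition number {cond:.3e}"
        )


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.asarray(sm.OLS(y, X).fit().params, dtype=float)


def fit_source_equation(series: ObservedSeries, emotion: str) -> SourceFit:
    """Least squares of dX(k) on {x(k-1), x(k-1)^2}, no intercept."""
    if len(series) < 3:
        raise InsufficientDataError(
            f"need at least 3 time points to fit a source equation, got {len(series)}"
        )
    x = series.column(emotion)
    dy = np.diff(x)
    xl = x[:-1]
    X = np.column_stack([xl, xl**2])
    names = (emotion, f"{emotion}^2")
    _check_design(X, names)
    coef = _ols(X, dy)
    c1, c2 = coef
    kappa = -c1 / c2 if c2 != 0 else np.inf
    return SourceFit(
        label=emotion,
        r_hat=float(c1),
        kappa_hat=float(kappa),
        coefficients=coef,
        regressor_names=names,
        design=X,
        response=dy,
        diagnostics=_diagnostics(X, dy, coef, names),
    )


def fit_target_equation(
    series: ObservedSeries, target_label: str, source_labels: Sequence[str]
) -> TargetFit:
    """Least squares of dY(k) on {y, y^2, x_1 y, ..., x_n y}, no intercept."""
    source_labels = tuple(source_labels)
    n = len(source_labels)
    if len(series) < n + 3:
        raise InsufficientDataError(
            f"need at least n + 3 = {n + 3} time points for {n} sources, got {len(series)}"
        )
    y = series.column(target_label)
    dy = np.diff(y)
    yl = y[:-1]
    cols = [yl, yl**2] + [series.column(lab)[:-1] * yl for lab in source_labels]
    X = np.column_stack(cols)
    names = (target_label, f"{target_label}^2") + tuple(
        f"{lab}*{target_label}" for lab in source_labels
    )
    _check_design(X, names)
    coef = _ols(X, dy)
    r_hat = float(coef[0])
    K_hat = float(-coef[0] / coef[1]) if coef[1] != 0 else np.inf
    psi = {lab: float(coef[2 + i] / r_hat) for i, lab in enumerate(source_labels)}
    return TargetFit(
        label=target_label,
        source_labels=source_labels,
        r_hat=r_hat,
        K_hat=K_hat,
        psi_hat=psi,
        coefficients=coef,
        regressor_names=names,
        design=X,
        response=dy,
        diagnostics=_diagnostics(X, dy, coef, names),
    )


def regression_diagnostics(fit: SourceFit | TargetFit) -> RegressionDiagnostics:
    """Recompute R^2, per-regressor VIF and overall F for a stored fit."""
    return _diagnostics(fit.design, fit.response, fit.coefficients, fit.regressor_names)


@dataclass(frozen=True)
class Anchor:
    """External information that splits the identified composites.

    Exactly one of:
      * ``kind="K"`` — the source capacity K_i is known (``value``);
      * ``kind="b"`` — the conversion proportion b_i is known (``value``);
      * ``kind="window"`` — fit the plain logistic difference equation on
        a pre-guidance slice ``window=(start, stop)`` of the series,
        where no transfer has begun (b = 0), so the fitted effective
        capacity *is* K_i.
    """

    kind: str
    value: float | None = None
    window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("K", "b", "window"):
            raise InvalidInputError(f"anchor kind must be 'K', 'b' or 'window', got {self.kind!r}")
        if self.kind in ("K", "b") and self.value is None:
            raise InvalidInputError(f"anchor kind {self.kind!r} requires a value")
        if self.kind == "window" and self.window is None:
            raise InvalidInputError("anchor kind 'window' requires a (start, stop) window")


@dataclass(frozen=True)
class ResolvedParameters:
    """Fully resolved model spec plus provenance of each quantity."""

    spec: TransferModelSpec
    composites: dict[str, dict[str, float]]
    provenance: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.spec.sources, start=1):
            rows += [(f"r_{i}", s.r), (f"K_{i}", s.K), (f"a_{i}", s.a), (f"b_{i}", s.b)]
        rows += [("r", self.spec.target.r), ("K", self.spec.target.K)]
        return pd.DataFrame(rows, columns=["parameter", "value"])


def _split_composites(label: str, kappa: float, psi: float,
                      anchor_kind: str, anchor_value: float) -> tuple[float, float, float]:
    """Return (K, b, a) from kappa = K/(1+b), psi = a b / K and one anchor."""
    if kappa <= 0:
        raise DomainError(
            f"source {label!r}: fitted effective capacity kappa = {kappa:.6g} is "
            "not positive; the fit is not a growth-saturating series"
        )
    if anchor_kind == "K":
        K = float(anchor_value)
        b = K / kappa - 1.0
    else:
        b = float(anchor_value)
        K = kappa * (1.0 + b)
    if not (0 < b < 1):
        raise DomainError(
            f"source {label!r}: anchor implies conversion proportion b = {b:.6g} "
            f"outside (0, 1) (kappa_hat = {kappa:.6g})"
        )
    a = psi * K / b
    if not (0 < a < 1):
        raise DomainError(
            f"source {label!r}: anchor implies transfer coefficient a = {a:.6g} "
            f"outside (0, 1) (psi_hat = {psi:.6g})"
        )
    return K, b, a


def resolve_parameters(
    source_fits: Sequence[SourceFit],
    target_fit: TargetFit,
    anchors: Mapping[str, Anchor],
    series: ObservedSeries | None = None,
    rel_tol: float = 1e-8,
) -> ResolvedParameters:
    """Split the identified composites into full (K_i, b_i, a_i) using anchors.

    Window anchors need ``series``. The result is validated: each
    K_i/(1+b_i) must reproduce kappa_hat_i and each a_i b_i/K_i must
    reproduce psi_hat_i within ``rel_tol``.
    """
    sources = []
    composites: dict[str, dict[str, float]] = {}
    provenance: dict[str, str] = {}
    for fit in source_fits:
        lab = fit.label
        if lab not in anchors:
            raise InvalidInputError(
                f"no anchor supplied for source {lab!r}; the regression identifies "
                "only K/(1+b) and a*b/K — supply a K, b or window anchor"
            )
        anchor = anchors[lab]
        psi = target_fit.psi_hat[lab]
        if anchor.kind == "window":
            if series is None:
                raise InvalidInputError("window anchors require the observed series")
            start, stop = anchor.window
            pre = series.window(start, stop)
            K_anchor = fit_source_equation(pre, lab).kappa_hat
            K, b, a = _split_composites(lab, fit.kappa_hat, psi, "K", K_anchor)
            provenance[lab] = (
                f"K anchored by plain-logistic fit on pre-guidance window "
                f"[{start}:{stop}] (K = {K_anchor:.6g}); b, a derived"
            )
        else:
            K, b, a = _split_composites(lab, fit.kappa_hat, psi, anchor.kind, anchor.value)
            provenance[lab] = f"{anchor.kind} supplied externally ({anchor.value}); rest derived"
        if abs(K / (1.0 + b) - fit.kappa_hat) > rel_tol * abs(fit.kappa_hat):
            raise DomainError(f"source {lab!r}: resolved K/(1+b) fails to reproduce kappa_hat")
        if abs(a * b / K - psi) > rel_tol * max(abs(psi), 1e-300):
            raise DomainError(f"source {lab!r}: resolved a*b/K fails to reproduce psi_hat")
        x0 = float(series.column(lab)[0]) if series is not None else fit.kappa_hat * 0.05
        sources.append(SourceEmotionSpec(label=lab, x0=x0, r=fit.r_hat, K=K, a=a, b=b))
        composites[lab] = {"kappa_hat": fit.kappa_hat, "psi_hat": psi}
    provenance[target_fit.label] = "r, K estimated by the target regression"
    y0 = (float(series.column(target_fit.label)[0]) if series is not None
          else target_fit.K_hat * 0.05)
    target = TargetEmotionSpec(label=target_fit.label, y0=y0,
                               r=target_fit.r_hat, K=target_fit.K_hat)
    spec = TransferModelSpec(sources=tuple(sources), target=target)
    return ResolvedParameters(spec=spec, composites=composites, provenance=provenance)


@dataclass(frozen=True)
class FitResult:
    """End-to-end estimation output: fits, resolved spec, fitted overlay."""

    resolved: ResolvedParameters
    source_fits: tuple[SourceFit, ...]
    target_fit: TargetFit
    fitted: Trajectory

    def diagnostics_table(self) -> pd.DataFrame:
        rows = []
        for fit in (*self.source_fits, self.target_fit):
            d = fit.diagnostics
            rows.append({
                "equation": fit.label,
                "r_squared": d.r_squared,
                "f_value": d.f_value,
                **{f"vif[{k}]": v for k, v in d.vif.items()},
            })
        return pd.DataFrame(rows)


def fit_pipeline(
    series: ObservedSeries,
    anchors: Mapping[str, Anchor],
    target_label: str,
    source_labels: Sequence[str] | None = None,
) -> FitResult:
    """Difference, regress, resolve, and re-simulate for overlay plots.

    The fitted overlay trajectory uses the unit-step difference
    recursion (the estimator's own model class) over the observed time
    span, starting from the first observed values.
    """
    if not series.cumulative:
        raise InvalidInputError("fit_pipeline requires a cumulative series; cumulate first")
    if source_labels is None:
        source_labels = tuple(l for l in series.labels if l != target_label)
    source_fits = tuple(fit_source_equation(series, lab) for lab in source_labels)
    target_fit = fit_target_equation(series, target_label, source_labels)
    resolved = resolve_parameters(source_fits, target_fit, anchors, series=series)
    horizon = float(len(series) - 1)
    fitted = integrate(resolved.spec, horizon=horizon, step=1.0, method="euler")
    return FitResult(resolved=resolved, source_fits=source_fits,
                     target_fit=target_fit, fitted=fitted)
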