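"""Difference-equation regression: recovery, diagnostics, anchors."""

import numpy as np
import pytest
import statsmodels.api as sm

from emotransfer import (
    Anchor,
    CollinearityError,
    DomainError,
    GeneratorConfig,
    InsufficientDataError,
    InvalidInputError,
    ObservedSeries,
    difference_series,
    fit_pipeline,
    fit_source_equation,
    fit_target_equation,
    generate_series,
    integrate,
    regression_diagnostics,
    resolve_parameters,
)


def _series_from_columns(labels, columns, cumulative=True):
    values = np.column_stack(columns)
    return ObservedSeries(times=np.arange(values.shape[0]), values=values,
                          labels=labels, cumulative=cumulative)


class TestDifferenceSeries:
    def test_constant_series_gives_zeros(self):
        s = _series_from_columns(("x",), [np.full(6, 7.0)])
        np.testing.assert_array_equal(difference_series(s, "x"), np.zeros(5))

    def test_hand_differenced_value_and_length_contract(self):
        s = _series_from_columns(("x",), [np.array([80.0, 127.6, 150.0])])
        d = difference_series(s, "x")
        assert d.shape == (2,)
        assert d[0] == pytest.approx(47.6)

    def test_too_short_series_rejected(self):
        s = _series_from_columns(("x",), [np.array([5.0])])
        with pytest.raises(InsufficientDataError):
            difference_series(s, "x")


class TestObservedSeriesValidation:
    def test_non_monotone_cumulative_rejected_with_location(self):
        with pytest.raises(InvalidInputError, match="decreases at index 2"):
            _series_from_columns(("x",), [np.array([5.0, 6.0, 4.0])])

    def test_non_positive_values_rejected(self):
        with pytest.raises(InvalidInputError):
            _series_from_columns(("x",), [np.array([0.0, 1.0, 2.0])])


class TestSourceEquation:
    def test_exact_recovery_from_generating_recursion(self):
        # recursion dx = 0.7 x - 0.0016625 x^2 encodes r=0.7, K=800, b=0.9,
        # because r (1 + b) / K = 0.0016625 and K/(1+b) = 421.0526...
        x = [80.0]
        for _ in range(15):
            xi = x[-1]
            x.append(xi + 0.7 * xi - 0.0016625 * xi**2)
        s = _series_from_columns(("x",), [np.array(x)])
        fit = fit_source_equation(s, "x")
        assert fit.r_hat == pytest.approx(0.7, rel=1e-8)
        assert fit.kappa_hat == pytest.approx(800.0 / 1.9, rel=1e-8)
        assert fit.diagnostics.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_plain_logistic_recursion_yields_capacity(self):
        x = [10.0]
        for _ in range(15):
            xi = x[-1]
            x.append(xi + 0.5 * xi * (1 - xi / 300.0))
        fit = fit_source_equation(_series_from_columns(("x",), [np.array(x)]), "x")
        assert fit.kappa_hat == pytest.approx(300.0, rel=1e-8)

    def test_collinear_design_raises_with_condition_number(self):
        # constant column makes x and x^2 proportional
        s = _series_from_columns(("x",), [np.full(8, 5.0)])
        with pytest.raises((CollinearityError, InsufficientDataError)):
            fit_source_equation(s, "x")

    def test_requires_three_points(self):
        s = _series_from_columns(("x",), [np.array([1.0, 2.0])])
        with pytest.raises(InsufficientDataError):
            fit_source_equation(s, "x")


class TestTargetEquation:
    def test_exact_recovery_from_generating_recursion(self, known_spec, recursion_series):
        fit = fit_target_equation(recursion_series, "positive", ("negative", "neutral"))
        assert fit.r_hat == pytest.approx(0.8, rel=1e-8)
        assert fit.K_hat == pytest.approx(300.0, rel=1e-8)
        assert fit.psi_hat["negative"] == pytest.approx(0.5 * 0.9 / 800.0, rel=1e-8)
        assert fit.psi_hat["neutral"] == pytest.approx(0.3 * 0.4 / 400.0, rel=1e-8)
        assert fit.diagnostics.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_negligible_transfer_yields_tiny_composites(self, known_spec):
        quiet = known_spec.with_coefficients(a=(1e-9, 1e-9), b=(0.9, 0.4))
        series = generate_series(GeneratorConfig(spec=quiet, mode="difference", horizon=15))
        fit = fit_target_equation(series, "positive", ("negative", "neutral"))
        assert abs(fit.psi_hat["negative"]) < 1e-10
        assert fit.K_hat == pytest.approx(300.0, rel=1e-6)

    def test_requires_n_plus_three_points(self, recursion_series):
        short = recursion_series.window(0, 4)
        with pytest.raises(InsufficientDataError):
            fit_target_equation(short, "positive", ("negative", "neutral"))


class TestDiagnostics:
    def test_agrees_with_reference_ols_implementation(self):
        # small worked dataset, cross-checked against statsmodels' own
        # uncentered R^2 and overall F for the no-intercept model
        rng = np.random.default_rng(42)
        x = np.linspace(10, 60, 8)
        y = 0.4 * x - 0.002 * x**2 + rng.normal(0, 0.5, 8)
        s = _series_from_columns(("x",), [np.cumsum(np.abs(y)) + 1.0])
        fit = fit_source_equation(s, "x")
        ref = sm.OLS(fit.response, fit.design).fit()
        d = regression_diagnostics(fit)
        assert d.r_squared == pytest.approx(ref.rsquared, rel=1e-10)
        assert d.f_value == pytest.approx(ref.fvalue, rel=1e-10)

    def test_orthogonal_regressors_have_unit_vif(self):
        X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        y = np.array([1.0, 1.1, 2.0, 2.1])
        from emotransfer.estimation import _diagnostics

        coef = np.linalg.lstsq(X, y, rcond=None)[0]
        d = _diagnostics(X, y, coef, ("u", "v"))
        assert d.vif["u"] == pytest.approx(1.0, abs=1e-12)
        assert d.vif["v"] == pytest.approx(1.0, abs=1e-12)

    def test_noise_lowers_r_squared(self, known_spec):
        clean = generate_series(GeneratorConfig(spec=known_spec, mode="difference",
                                                horizon=15, sigma=0.0))
        noisy = generate_series(GeneratorConfig(spec=known_spec, mode="difference",
                                                horizon=15, sigma=0.1, seed=3))
        r2_clean = fit_source_equation(clean, "negative").diagnostics.r_squared
        r2_noisy = fit_source_equation(noisy, "negative").diagnostics.r_squared
        assert r2_clean > r2_noisy


class TestResolveParameters:
    def test_algebraic_inversion_of_composites(self, recursion_series):
        sfits = [fit_source_equation(recursion_series, lab) for lab in ("negative", "neutral")]
        tfit = fit_target_equation(recursion_series, "positive", ("negative", "neutral"))
        resolved = resolve_parameters(
            sfits, tfit,
            {"negative": Anchor("K", value=800.0), "neutral": Anchor("K", value=400.0)},
            series=recursion_series,
        )
        src = {s.label: s for s in resolved.spec.sources}
        assert src["negative"].b == pytest.approx(0.9, rel=1e-6)
        assert src["negative"].a == pytest.approx(0.5, rel=1e-6)
        assert src["neutral"].b == pytest.approx(0.4, rel=1e-6)
        assert src["neutral"].a == pytest.approx(0.3, rel=1e-6)

    def test_b_anchor_recovers_capacity(self, recursion_series):
        sfits = [fit_source_equation(recursion_series, lab) for lab in ("negative", "neutral")]
        tfit = fit_target_equation(recursion_series, "positive", ("negative", "neutral"))
        resolved = resolve_parameters(
            sfits, tfit,
            {"negative": Anchor("b", value=0.9), "neutral": Anchor("b", value=0.4)},
            series=recursion_series,
        )
        src = {s.label: s for s in resolved.spec.sources}
        assert src["negative"].K == pytest.approx(800.0, rel=1e-8)
        assert src["neutral"].K == pytest.approx(400.0, rel=1e-8)

    def test_anchor_at_kappa_implies_zero_b_and_fails(self, recursion_series):
        sfits = [fit_source_equation(recursion_series, lab) for lab in ("negative", "neutral")]
        tfit = fit_target_equation(recursion_series, "positive", ("negative", "neutral"))
        kappa = sfits[0].kappa_hat
        with pytest.raises(DomainError, match="b ="):
            resolve_parameters(
                sfits, tfit,
                {"negative": Anchor("K", value=kappa), "neutral": Anchor("K", value=400.0)},
                series=recursion_series,
            )

    def test_missing_anchor_is_an_explicit_error(self, recursion_series):
        sfits = [fit_source_equation(recursion_series, lab) for lab in ("negative", "neutral")]
        tfit = fit_target_equation(recursion_series, "positive", ("negative", "neutral"))
        with pytest.raises(InvalidInputError, match="anchor"):
            resolve_parameters(sfits, tfit, {"negative": Anchor("K", value=800.0)},
                               series=recursion_series)

    def test_identifiability_two_anchors_same_observable_trajectories(self, recursion_series):
        # any admissible K > kappa yields identical observable dynamics
        sfits = [fit_source_equation(recursion_series, lab) for lab in ("negative", "neutral")]
        tfit = fit_target_equation(recursion_series, "positive", ("negative", "neutral"))
        trajectories = []
        for K1 in (700.0, 800.0):
            resolved = resolve_parameters(
                sfits, tfit,
                {"negative": Anchor("K", value=K1), "neutral": Anchor("K", value=400.0)},
                series=recursion_series,
            )
            trajectories.append(integrate(resolved.spec, horizon=15.0, method="euler").amounts)
        np.testing.assert_allclose(trajectories[0], trajectories[1], rtol=1e-8)


class TestFitPipeline:
    def test_round_trip_reproduces_all_composites(self, known_spec, recursion_series):
        result = fit_pipeline(
            recursion_series,
            {"negative": Anchor("K", value=800.0), "neutral": Anchor("K", value=400.0)},
            target_label="positive",
        )
        spec = result.resolved.spec
        for est, true in zip(spec.sources, known_spec.sources):
            assert est.r == pytest.approx(true.r, rel=1e-6)
            assert est.K / (1 + est.b) == pytest.approx(true.K / (1 + true.b), rel=1e-6)
            assert est.a * est.b / est.K == pytest.approx(true.a * true.b / true.K, rel=1e-6)
        assert spec.target.K == pytest.approx(300.0, rel=1e-6)
        # overlay trajectory reproduces the observations exactly (same model class)
        np.testing.assert_allclose(result.fitted.amounts, recursion_series.values, rtol=1e-8)

    def test_window_anchor_uses_pre_guidance_logistic_fit(self, known_spec):
        # pre-guidance: plain logistic (no conversion) for 3 steps — short
        # enough that no source exceeds its compressed capacity K/(1+b)
        # when transfer switches on; the window fit recovers K directly
        from emotransfer.model import integrate as _int

        pre = _int(known_spec.with_coefficients(a=(1e-12, 1e-12), b=(1e-12, 1e-12)),
                   horizon=3.0, method="euler")
        post_spec = type(known_spec)(
            sources=tuple(
                type(s)(s.label, float(x0), s.r, s.K, a=s.a, b=s.b)
                for s, x0 in zip(known_spec.sources, pre.terminal[:2])
            ),
            target=type(known_spec.target)(
                known_spec.target.label, float(pre.terminal[2]),
                known_spec.target.r, known_spec.target.K,
            ),
        )
        post = generate_series(GeneratorConfig(spec=post_spec, mode="difference", horizon=15))
        values = np.vstack([pre.amounts[:-1], post.values])
        series = ObservedSeries(times=np.arange(values.shape[0]), values=values,
                                labels=known_spec.labels)
        window_fit = fit_source_equation(series.window(0, 4), "negative")
        assert window_fit.kappa_hat == pytest.approx(800.0, rel=1e-4)

    def test_ode_sampled_data_recovery_improves_with_finer_sampling(self, known_spec):
        errors = []
        for step in (1.0, 0.25):
            traj = integrate(known_spec, horizon=12.0, step=step)
            series = ObservedSeries(times=np.arange(len(traj)), values=traj.amounts,
                                    labels=known_spec.labels)
            fit = fit_source_equation(series, "negative")
            errors.append(abs(fit.kappa_hat - 800.0 / 1.9) / (800.0 / 1.9))
        assert errors[1] < errors[0]
        assert errors[1] < 0.02
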