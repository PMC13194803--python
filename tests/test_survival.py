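"""Parametric survival families: evaluation, least-squares fitting, selection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirvcea.survival import (
    FAMILIES,
    ParametricSurvivalFitter,
    ParametricSurvivalModel,
    FitDiagnostics,
    fit_all_families,
    fit_model,
    select_model,
    survival_at,
)

#: reference parameter sets, one per family, used across fitting tests
REFERENCE_MODELS = {
    "exponential": ParametricSurvivalModel("exponential", (0.12,)),
    "weibull": ParametricSurvivalModel("weibull", (1.4, 8.0)),
    "gompertz": ParametricSurvivalModel("gompertz", (0.08, 0.09)),
    "loglogistic": ParametricSurvivalModel("loglogistic", (1.8, 5.62)),
    "lognormal": ParametricSurvivalModel("lognormal", (1.9, 0.9)),
}


def _points(model, t):
    return pd.DataFrame({"time_months": t, "survival": model.survival(np.asarray(t, float))})


class TestSurvivalAt:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_survival_at_zero_is_one(self, family):
        assert survival_at(REFERENCE_MODELS[family], 0.0) == pytest.approx(1.0)

    def test_loglogistic_median_at_scale(self):
        model = ParametricSurvivalModel("loglogistic", (2.0, 5.62))
        assert survival_at(model, 5.62) == pytest.approx(0.5)

    def test_weibull_shape_one_reduces_to_exponential(self):
        model = ParametricSurvivalModel("weibull", (1.0, 10.0))
        assert survival_at(model, 10.0) == pytest.approx(math.exp(-1.0))
        expo = ParametricSurvivalModel("exponential", (0.1,))
        t = np.linspace(0, 40, 30)
        np.testing.assert_allclose(model.survival(t), expo.survival(t), rtol=1e-12)

    def test_closed_forms_against_independent_arithmetic(self):
        t = 7.3
        assert survival_at(REFERENCE_MODELS["exponential"], t) == pytest.approx(
            math.exp(-0.12 * t)
        )
        assert survival_at(REFERENCE_MODELS["gompertz"], t) == pytest.approx(
            math.exp(-(0.09 / 0.08) * (math.exp(0.08 * t) - 1.0))
        )
        from scipy.stats import norm

        assert survival_at(REFERENCE_MODELS["lognormal"], t) == pytest.approx(
            1.0 - norm.cdf((math.log(t) - 1.9) / 0.9)
        )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            survival_at(REFERENCE_MODELS["weibull"], -1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ParametricSurvivalModel("weibull", (-1.0, 5.0))
        with pytest.raises(ValueError):
            ParametricSurvivalModel("nope", (1.0,))

    @pytest.mark.parametrize("family", FAMILIES)
    def test_median_closed_form(self, family):
        model = REFERENCE_MODELS[family]
        assert survival_at(model, model.median()) == pytest.approx(0.5, abs=1e-9)


class TestFitModel:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_recovers_self_generated_parameters(self, family):
        truth = REFERENCE_MODELS[family]
        points = _points(truth, np.arange(25.0))
        model, diag = fit_model(points, family)
        assert diag.converged
        assert diag.ssr < 1e-10
        np.testing.assert_allclose(model.params, truth.params, rtol=1e-6)

    def test_nested_weibull_vs_exponential(self):
        # on exponential data the richer Weibull cannot do worse in SSR,
        # but BIC's heavier penalty prefers the exponential
        truth = REFERENCE_MODELS["exponential"]
        rng = np.random.default_rng(5)
        t = np.arange(25.0)
        s = np.clip(truth.survival(t) + rng.normal(0, 0.01, 25), 0, 1)
        s = np.minimum.accumulate(s)
        points = pd.DataFrame({"time_months": t, "survival": s})
        _, d_exp = fit_model(points, "exponential")
        _, d_wei = fit_model(points, "weibull")
        assert d_wei.ssr <= d_exp.ssr + 1e-12
        assert d_exp.bic < d_wei.bic

    def test_flat_curve_flagged_non_informative(self):
        points = pd.DataFrame({"time_months": np.arange(10.0), "survival": np.ones(10)})
        model, diag = fit_model(points, "weibull")
        assert model is None
        assert not diag.converged
        assert math.isinf(diag.aic) and math.isinf(diag.bic)

    def test_input_validation(self):
        ok = _points(REFERENCE_MODELS["weibull"], np.arange(25.0))
        with pytest.raises(ValueError):
            fit_model(ok.iloc[:2], "weibull")
        bad = ok.copy()
        bad.loc[3, "survival"] = 1.5
        with pytest.raises(ValueError):
            fit_model(bad, "weibull")

    @pytest.mark.parametrize("family", FAMILIES)
    def test_fitted_model_monotone_non_increasing(self, family):
        truth = REFERENCE_MODELS[family]
        rng = np.random.default_rng(7)
        t = np.arange(25.0)
        s = np.minimum.accumulate(np.clip(truth.survival(t) + rng.normal(0, 0.02, 25), 0, 1))
        model, diag = fit_model(pd.DataFrame({"time_months": t, "survival": s}), family)
        assert diag.converged
        grid = np.linspace(0.0, 60.0, 2001)
        values = model.survival(grid)
        assert np.all(np.diff(values) <= 1e-12)
        assert np.all((values >= 0) & (values <= 1))


class TestSelectModel:
    def _diag(self, family, ssr, aic, bic, k=2):
        return FitDiagnostics(family, ssr, aic, bic, 25, k, True)

    def test_lowest_aic_wins(self):
        fits = [
            (REFERENCE_MODELS["weibull"], self._diag("weibull", 0.2, 12.0, 13.0)),
            (REFERENCE_MODELS["loglogistic"], self._diag("loglogistic", 0.1, 10.0, 11.0)),
            (REFERENCE_MODELS["lognormal"], self._diag("lognormal", 0.3, 15.0, 16.0)),
        ]
        chosen, report = select_model(fits)
        assert chosen.family == "loglogistic"
        assert report.loc[report["chosen"], "family"].iloc[0] == "loglogistic"

    def test_noise_free_loglogistic_selected_among_all_families(self, noise_free_curves):
        chosen, report = select_model(fit_all_families(noise_free_curves[("mirv", "pfs")]))
        assert chosen.family == "loglogistic"
        assert len(report) == len(FAMILIES)

    def test_exact_tie_broken_by_declared_family_order(self):
        d1 = self._diag("weibull", 0.1, 10.0, 11.0)
        d2 = self._diag("loglogistic", 0.1, 10.0, 11.0)
        chosen, _ = select_model(
            [(REFERENCE_MODELS["loglogistic"], d2), (REFERENCE_MODELS["weibull"], d1)]
        )
        assert chosen.family == "weibull"  # weibull precedes loglogistic in FAMILIES

    def test_near_tie_broken_by_bic(self):
        d1 = self._diag("weibull", 0.1, 10.000, 12.0)
        d2 = self._diag("loglogistic", 0.1, 10.002, 11.0)  # within the 0.01 AIC tie band
        chosen, _ = select_model(
            [(REFERENCE_MODELS["weibull"], d1), (REFERENCE_MODELS["loglogistic"], d2)]
        )
        assert chosen.family == "loglogistic"

    def test_no_converged_fits_errors(self):
        diag = FitDiagnostics("weibull", math.inf, math.inf, math.inf, 10, 2, False)
        with pytest.raises(ValueError):
            select_model([(None, diag)])


class TestParametricSurvivalFitter:
    def test_sklearn_estimator_protocol(self, noise_free_curves):
        fitter = ParametricSurvivalFitter()
        assert fitter.get_params()["aic_tie_tol"] == 0.01
        fitter.set_params(aic_tie_tol=0.05)
        assert fitter.get_params()["aic_tie_tol"] == 0.05
        with pytest.raises(ValueError):
            fitter.set_params(bogus=1)
        fitter.set_params(aic_tie_tol=0.01)
        fitter.fit(noise_free_curves[("standard", "os")])
        assert fitter.model_.family == "weibull"
        t = np.array([0.0, 6.0, 12.0])
        np.testing.assert_allclose(fitter.predict(t), fitter.model_.survival(t))

    def test_predict_before_fit_raises(self):
        with pytest.raises(AttributeError):
            ParametricSurvivalFitter().predict([1.0])

    def test_fit_accepts_separate_arrays(self):
        truth = REFERENCE_MODELS["weibull"]
        t = np.arange(25.0)
        fitter = ParametricSurvivalFitter().fit(t, truth.survival(t))
        assert fitter.model_.family == "weibull"


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    shape=st.floats(0.5, 4.0),
    scale=st.floats(1.0, 30.0),
    t=st.floats(0.0, 120.0),
)
def test_survival_bounds_property(shape, scale, t):
    """S(t) stays in [0,1] and never exceeds S at an earlier time."""
    for family in ("weibull", "loglogistic"):
        model = ParametricSurvivalModel(family, (shape, scale))
        s = survival_at(model, t)
        assert 0.0 <= s <= 1.0
        assert s <= survival_at(model, t / 2.0) + 1e-12
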