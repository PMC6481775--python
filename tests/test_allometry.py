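"""Nonlinear allometric fits, AIC comparison, SMA regression, sigmoid fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from allohet import (
    compare_models_aic,
    evaluate,
    fit_fruit_allometry,
    fit_growth_allometry,
    fit_sigmoid_growth,
    fit_sma,
)
from allohet import test_slope as sma_slope_test
from allohet import allometry
from allohet.config import ACCESSION_FRUIT_COEFFS, ACCESSION_GROWTH_COEFFS


def _masses(rng, n=400):
    return 10 ** rng.normal(1.6, 0.7, n)


NOISE_FREE_CASES = [
    ("growth", "power_mass_corrected", (0.022, 1.483, -0.164)),
    ("growth", "power_fixed", (0.3, 0.75)),
    ("fruit", "inverse_quadratic", (0.155, 0.0022, 1.292e-5)),
    ("fruit", "ricker", (1.5, 0.004)),
]


@pytest.mark.parametrize("kind,form,coeffs", NOISE_FREE_CASES)
def test_noise_free_identity_recovers_generative_coefficients(kind, form, coeffs, rng):
    M = _masses(rng)
    func = allometry._FORMS[form][0]
    Y = func(M, *coeffs)
    fitter = fit_growth_allometry if kind == "growth" else fit_fruit_allometry
    model = fitter(M, Y, form)
    for key, truth in zip("abc", coeffs):
        assert model.coefficients[key] == pytest.approx(truth, rel=1e-6)
    lo_hi = model.ci95
    for key in model.coefficients:
        assert lo_hi[key][0] <= model.coefficients[key] <= lo_hi[key][1]


class TestEvaluate:
    def test_growth_at_unit_mass_equals_scale_coefficient(self, growth_model):
        # at M = 1 mg the mass-corrected exponent is irrelevant (log10 1 = 0)
        assert evaluate(growth_model, 1.0) == pytest.approx(0.022)

    def test_growth_at_100mg(self, growth_model):
        # 0.022 * 100**(1.483 - 0.328) computed independently
        assert evaluate(growth_model, 100.0) == pytest.approx(4.4918235, rel=1e-6)

    def test_fruit_at_100mg(self, fruit_model):
        # 100 / (0.155 + 0.22 + 0.1292) computed independently
        assert evaluate(fruit_model, 100.0) == pytest.approx(198.3339944, rel=1e-6)

    def test_nonpositive_mass_rejected(self, growth_model):
        with pytest.raises(ValueError):
            evaluate(growth_model, 0.0)
        with pytest.raises(ValueError):
            evaluate(growth_model, np.array([1.0, -2.0]))


class TestModelShape:
    def test_fruit_curve_peak_at_sqrt_a_over_c(self, fruit_model):
        a = fruit_model.coefficients["a"]
        c = fruit_model.coefficients["c"]
        peak = np.sqrt(a / c)
        assert peak == pytest.approx(109.5303795, rel=1e-6)
        grid = np.linspace(1.3, 2218, 200001)
        assert grid[np.argmax(evaluate(fruit_model, grid))] == pytest.approx(peak, abs=0.1)

    def test_fruit_curve_rises_then_falls(self, fruit_model):
        grid = np.linspace(1.3, 2218, 5001)
        vals = evaluate(fruit_model, grid)
        ipeak = np.argmax(vals)
        assert 0 < ipeak < len(grid) - 1
        assert np.all(np.diff(vals[: ipeak + 1]) > 0)
        assert np.all(np.diff(vals[ipeak:]) < 0)

    def test_growth_curve_concavity(self, growth_model):
        # log-log concavity holds over the full observed mass range (c < 0);
        # linear-space concavity holds above ~13 mg (the curve is locally
        # steeper than linear at the very smallest masses)
        x = np.linspace(np.log10(1.3), np.log10(2218), 2001)
        ly = np.log10(evaluate(growth_model, 10**x))
        assert np.all(np.diff(ly, 2) <= 1e-12)
        grid = np.linspace(13.0, 2218.0, 20001)
        vals = evaluate(growth_model, grid)
        assert np.all(np.diff(vals, 2) <= 1e-9)


class TestAIC:
    def test_model_vs_itself_is_zero(self, rng):
        M = _masses(rng)
        Y = evaluate_model = allometry._power_fixed(M, 0.3, 0.75) * np.exp(
            rng.normal(0, 0.1, M.size)
        )
        m = fit_growth_allometry(M, Y, "power_fixed")
        assert compare_models_aic(m, m) == 0.0

    def test_mass_corrected_form_wins_on_curved_data(self, rng):
        M = _masses(rng, 450)
        Y = allometry._power_mass_corrected(M, *ACCESSION_GROWTH_COEFFS) * 10 ** rng.normal(
            0, 0.05, M.size
        )
        full = fit_growth_allometry(M, Y, "power_mass_corrected")
        fixed = fit_growth_allometry(M, Y, "power_fixed")
        assert compare_models_aic(fixed, full) > 0

    def test_differing_n_rejected(self, rng):
        M = _masses(rng)
        Y = allometry._power_fixed(M, 0.3, 0.75)
        m1 = fit_growth_allometry(M, Y, "power_fixed")
        m2 = fit_growth_allometry(M[:100], Y[:100], "power_fixed")
        with pytest.raises(ValueError):
            compare_models_aic(m1, m2)

    def test_ranking_invariant_to_additive_constant(self, rng):
        # the Gaussian AIC is defined up to a shared constant; the ordering
        # of two models on the same data must not depend on it
        M = _masses(rng, 200)
        Y = allometry._power_mass_corrected(M, *ACCESSION_GROWTH_COEFFS) * 10 ** rng.normal(
            0, 0.1, M.size
        )
        full = fit_growth_allometry(M, Y, "power_mass_corrected")
        fixed = fit_growth_allometry(M, Y, "power_fixed")
        const = 123.456
        shifted = compare_models_aic(fixed, full)
        assert shifted == pytest.approx((fixed.aic + const) - (full.aic + const))


class TestSMA:
    def test_noise_free_line(self):
        x = np.linspace(0, 3, 50)
        fit = fit_sma(x, 0.75 * x + 1.0)
        assert fit.slope == pytest.approx(0.75)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_slope_magnitude_is_sd_ratio(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        y = 0.6 * x + rng.normal(scale=0.5, size=30)
        fit = fit_sma(x, y)
        assert abs(fit.slope) == pytest.approx(y.std(ddof=1) / x.std(ddof=1), rel=1e-9)

    def test_matches_major_axis_of_standardized_data_oracle(self, rng):
        # independent oracle: first principal axis of the standardized data,
        # mapped back to the original scale
        x = rng.normal(size=60)
        y = 0.8 * x + rng.normal(scale=0.4, size=60)
        xs = (x - x.mean()) / x.std(ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        cov = np.cov(np.vstack([xs, ys]))
        w, v = np.linalg.eigh(cov)
        axis = v[:, np.argmax(w)]
        oracle = (axis[1] / axis[0]) * y.std(ddof=1) / x.std(ddof=1)
        assert fit_sma(x, y).slope == pytest.approx(oracle, rel=1e-9)

    def test_exact_hypothesized_slope_gives_p_one(self):
        x = np.linspace(0, 3, 40)
        fit = fit_sma(x, 0.75 * x + 1.0)
        assert sma_slope_test(fit, 0.75) == pytest.approx(1.0)

    def test_steeper_slope_detected_against_three_quarters(self, rng):
        x = rng.normal(1.5, 0.7, 400)
        y = 0.9 * x + rng.normal(scale=0.05, size=400)
        fit = fit_sma(x, y)
        assert sma_slope_test(fit, 0.75) < 0.01

    def test_p_invariant_to_axis_exchange(self, rng):
        x = rng.normal(size=50)
        y = 0.7 * x + rng.normal(scale=0.3, size=50)
        p_xy = sma_slope_test(fit_sma(x, y), 0.8)
        p_yx = sma_slope_test(fit_sma(y, x), 1 / 0.8)
        assert p_xy == pytest.approx(p_yx, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_sma(np.ones(10), np.arange(10.0))

    def test_group_slope_difference_detects_distinct_slopes(self, rng):
        x1 = rng.normal(1.5, 0.7, 400)
        y1 = 0.75 * x1 + rng.normal(scale=0.05, size=400)
        x2 = rng.normal(1.5, 0.7, 400)
        y2 = 0.95 * x2 + rng.normal(scale=0.05, size=400)
        p_diff = allometry.slope_difference(fit_sma(x1, y1), fit_sma(x2, y2))
        assert p_diff < 0.01
        p_same = allometry.slope_difference(fit_sma(x1, y1), fit_sma(x1, y1))
        assert p_same == pytest.approx(1.0)


class TestSigmoid:
    def test_time_translation_equivariance(self):
        t = np.arange(0, 60, 2.0)
        m = 100.0 / (1.0 + np.exp(-0.3 * (t - 20.0)))
        base = fit_sigmoid_growth(t, m)
        shifted = fit_sigmoid_growth(t + 5.0, m)
        assert shifted.t0 == pytest.approx(base.t0 + 5.0, rel=1e-6)
        assert shifted.K == pytest.approx(base.K, rel=1e-9)
        assert shifted.r == pytest.approx(base.r, rel=1e-6)

    def test_noisy_recovery_of_asymptote(self):
        from allohet import synthetic_data as sd

        Ks = []
        for k in range(100):
            t, m = sd.generate_growth_series(
                100.0, 20.0, 0.3, np.arange(0, 60, 2.0), noise_sd=2.0, seed=k
            )
            Ks.append(fit_sigmoid_growth(t, m).K)
        assert np.median(Ks) == pytest.approx(100.0, rel=0.02)


def test_model_json_round_trip(tmp_path, rng):
    M = _masses(rng)
    Y = allometry._power_mass_corrected(M, *ACCESSION_GROWTH_COEFFS)
    model = fit_growth_allometry(M, Y)
    path = tmp_path / "model.json"
    allometry.save_model(model, path)
    back = allometry.load_model(path)
    assert back == model


def test_fit_rejects_nonpositive_and_tiny_inputs():
    with pytest.raises(ValueError):
        fit_growth_allometry([1, 2, -3] + [4] * 10, [1] * 13)
    with pytest.raises(ValueError):
        fit_growth_allometry([1, 2, 3], [1, 2, 3])
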