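"""Allometric model fitting: nonlinear least squares, SMA regression,
logistic growth curves.

Two trait~mass relationships are supported for each trait:

* growth rate G (mg/d) vs vegetative dry mass M (mg):
  ``power_mass_corrected``  g(M) = a * M**(b + c*log10(M))  — a power law
  whose exponent varies linearly with log10 mass, giving a concave log-log
  curve when c < 0;
  ``power_fixed``           g(M) = a * M**b.
* fruit number F vs M:
  ``inverse_quadratic``     f(M) = M / (a + b*M + c*M**2)  — a right-skewed
  hump with an interior maximum at M = sqrt(a/c);
  ``ricker``                f(M) = a * M * exp(-b*M).

Fitting is by nonlinear least squares on the untransformed trait values
(``scipy.optimize.curve_fit``) from linearization-based starting values
with a multi-start fallback.  The log base in the mass-corrected exponent
is 10 throughout.

Standardized major axis (SMA) regression on log10-transformed data is
provided separately for estimating allometric exponents, with the
one-sample slope test (e.g. against the metabolic-scaling value 3/4) and a
two-group slope comparison.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

__all__ = [
    "AllometricModel",
    "SMAFit",
    "SigmoidFit",
    "FitError",
    "fit_growth_allometry",
    "fit_fruit_allometry",
    "evaluate",
    "compare_models_aic",
    "fit_sma",
    "test_slope",
    "slope_difference",
    "fit_sigmoid_growth",
    "save_model",
    "load_model",
]

GROWTH_FORMS = ("power_mass_corrected", "power_fixed")
FRUIT_FORMS = ("inverse_quadratic", "ricker")


class FitError(RuntimeError):
    """Nonlinear fit failed to converge or produced an invalid model."""


def _power_mass_corrected(M, a, b, c):
    return a * M ** (b + c * np.log10(M))


def _power_fixed(M, a, b):
    return a * M**b


def _inverse_quadratic(M, a, b, c):
    return M / (a + b * M + c * M * M)


def _ricker(M, a, b):
    return a * M * np.exp(-b * M)


_FORMS = {
    "power_mass_corrected": (_power_mass_corrected, 3),
    "power_fixed": (_power_fixed, 2),
    "inverse_quadratic": (_inverse_quadratic, 3),
    "ricker": (_ricker, 2),
}


@dataclass
class AllometricModel:
    """A fitted trait~mass relationship."""

    form: str
    coefficients: Dict[str, float]
    ci95: Dict[str, Tuple[float, float]]
    n: int
    rss: float
    aic: float
    fitted_on: str = "accessions"

    def __call__(self, M):
        return evaluate(self, M)


def evaluate(model: AllometricModel, M):
    """Closed-form evaluation of a fitted model at mass M (mg); M must be > 0."""
    M = np.asarray(M, dtype=float)
    if np.any(M <= 0) or not np.all(np.isfinite(M)):
        raise ValueError("mass must be positive and finite")
    func, _ = _FORMS[model.form]
    out = func(M, *(model.coefficients[k] for k in sorted(model.coefficients)))
    return float(out) if out.ndim == 0 else out


def _aic_gaussian(n: int, rss: float, k_coeff: int) -> float:
    # Gaussian-likelihood AIC up to the additive constant n*log(2*pi) + n,
    # which is identical for models compared on the same data; the residual
    # variance counts as one estimated parameter.  rss is floored to keep a
    # numerically perfect fit finite.
    return n * math.log(max(rss, 1e-300) / n) + 2 * (k_coeff + 1)


def _finalize(form, func, popt, pcov, M, Y, fitted_on) -> AllometricModel:
    resid = Y - func(M, *popt)
    rss = float(resid @ resid)
    n = len(M)
    k = len(popt)
    names = "abc"[:k]
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    tcrit = stats.t.ppf(0.975, max(n - k, 1))
    ci = {
        names[i]: (float(popt[i] - tcrit * se[i]), float(popt[i] + tcrit * se[i]))
        for i in range(k)
    }
    model = AllometricModel(
        form=form,
        coefficients={names[i]: float(popt[i]) for i in range(k)},
        ci95=ci,
        n=n,
        rss=rss,
        aic=_aic_gaussian(n, rss, k),
        fitted_on=fitted_on,
    )
    if form == "inverse_quadratic":
        a, b, c = popt
        denom = a + b * M + c * M * M
        if np.any(denom <= 0):
            raise FitError(
                "inverse-quadratic denominator crosses zero inside the data range"
            )
    if model.coefficients["a"] <= 0:
        raise FitError(f"fitted scale coefficient a={model.coefficients['a']} <= 0")
    return model


def _validate_xy(M, Y, min_n=10):
    M = np.asarray(M, dtype=float)
    Y = np.asarray(Y, dtype=float)
    ok = np.isfinite(M) & np.isfinite(Y)
    M, Y = M[ok], Y[ok]
    if np.any(M <= 0) or np.any(Y <= 0):
        raise ValueError("mass and trait values must be strictly positive")
    if len(M) < min_n:
        raise ValueError(f"need >= {min_n} paired observations, got {len(M)}")
    if len(np.unique(M)) < 3:
        raise ValueError("need >= 3 distinct mass values")
    return M, Y


def _growth_start(M, Y, form):
    # log10 G = log10 a + b x + c x^2 with x = log10 M: a quadratic (or
    # linear) polynomial fit supplies excellent starting values.
    x = np.log10(M)
    y = np.log10(Y)
    if form == "power_mass_corrected":
        c2, b1, a0 = np.polyfit(x, y, 2)
        return [10.0**a0, b1, c2]
    b1, a0 = np.polyfit(x, y, 1)
    return [10.0**a0, b1]


def _fruit_start(M, Y, form):
    if form == "inverse_quadratic":
        # M/F = a + b M + c M^2 is linear in (1, M, M^2)
        z = M / Y
        X = np.column_stack([np.ones_like(M), M, M * M])
        coef, *_ = np.linalg.lstsq(X, z, rcond=None)
        a, b, c = coef
        return [max(a, 1e-6), max(b, 1e-8), max(c, 1e-12)]
    # Ricker: log(F/M) = log a - b M
    b1, a0 = np.polyfit(M, np.log(Y / M), 1)
    return [math.exp(a0), max(-b1, 1e-8)]


def _multistart_fit(func, M, Y, start, form, fitted_on):
    starts = [start]
    for factor in (0.3, 3.0):
        starts.append([s * factor if i == 0 else s for i, s in enumerate(start)])
    for factor in (0.5, 2.0):
        starts.append([s * factor for s in start])
    last_err: Optional[Exception] = None
    best = None
    for s0 in starts:
        try:
            popt, pcov = optimize.curve_fit(func, M, Y, p0=s0, maxfev=20000)
            model = _finalize(form, func, popt, pcov, M, Y, fitted_on)
        except (RuntimeError, FitError, ValueError) as err:  # non-convergence
            last_err = err
            continue
        if best is None or model.rss < best.rss:
            best = model
    if best is None:
        raise FitError(
            f"nonlinear fit of form '{form}' failed after "
            f"{len(starts)} starts: {last_err}"
        )
    return best


def fit_growth_allometry(
    M: Sequence[float],
    G: Sequence[float],
    form: str = "power_mass_corrected",
    fitted_on: str = "accessions",
) -> AllometricModel:
    """Least-squares fit of growth rate vs mass.

    Parameters
    ----------
    M, G
        Paired vegetative dry mass (mg) and growth rate (mg/d); >= 10 pairs.
    form
        ``power_mass_corrected`` (default) or ``power_fixed``.
    """
    if form not in GROWTH_FORMS:
        raise ValueError(f"growth form must be one of {GROWTH_FORMS}")
    M, G = _validate_xy(M, G)
    func, _ = _FORMS[form]
    return _multistart_fit(func, M, G, _growth_start(M, G, form), form, fitted_on)


def fit_fruit_allometry(
    M: Sequence[float],
    F: Sequence[float],
    form: str = "inverse_quadratic",
    fitted_on: str = "accessions",
) -> AllometricModel:
    """Least-squares fit of fruit number vs mass (``inverse_quadratic``
    default, ``ricker`` alternative)."""
    if form not in FRUIT_FORMS:
        raise ValueError(f"fruit form must be one of {FRUIT_FORMS}")
    M, F = _validate_xy(M, F)
    func, _ = _FORMS[form]
    return _multistart_fit(func, M, F, _fruit_start(M, F, form), form, fitted_on)


def compare_models_aic(
    alternative: AllometricModel, retained: AllometricModel
) -> float:
    """Delta AIC = AIC(alternative) - AIC(retained); both models must have
    been fitted on the same data (checked via n).  Positive values favour
    the retained model."""
    if alternative.n != retained.n:
        raise ValueError(
            f"models fitted on different data: n={alternative.n} vs {retained.n}"
        )
    return float(alternative.aic - retained.aic)


# ---------------------------------------------------------------------------
# Standardized major axis regression (log-log allometric exponents)


@dataclass
class SMAFit:
    """SMA line fit on (typically log10-transformed) data.

    slope magnitude equals sd(y)/sd(x) by construction; the sign is the sign
    of the correlation.
    """

    slope: float
    intercept: float
    r2: float
    n: int
    slope_ci95: Tuple[float, float]
    _x: np.ndarray = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)


def fit_sma(log_x: Sequence[float], log_y: Sequence[float]) -> SMAFit:
    x = np.asarray(log_x, dtype=float)
    y = np.asarray(log_y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("SMA needs >= 3 finite pairs")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("SMA undefined for zero-variance data")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = math.copysign(sy / sx, r if r != 0 else 1.0)
    intercept = float(y.mean() - slope * x.mean())
    # Warton et al. (2006): CI via B = F(0.95; 1, n-2) * (1 - r^2)/(n - 2)
    B = stats.f.ppf(0.95, 1, n - 2) * (1.0 - r * r) / (n - 2)
    lo = slope * (math.sqrt(B + 1.0) - math.sqrt(B))
    hi = slope * (math.sqrt(B + 1.0) + math.sqrt(B))
    return SMAFit(
        slope=float(slope),
        intercept=intercept,
        r2=r * r,
        n=n,
        slope_ci95=(min(lo, hi), max(lo, hi)),
        _x=x,
        _y=y,
    )


def test_slope(fit: SMAFit, hypothesized: float) -> float:
    """Two-sided p-value for H0: SMA slope = hypothesized.

    Standard SMA one-sample test: under H0 the residual axis y - b0*x and
    the fitted axis y + b0*x are uncorrelated; their sample correlation is
    referred to a t distribution with n - 2 df.
    """
    x, y = fit._x, fit._y
    resid = y - hypothesized * x
    axis = y + hypothesized * x
    scale = max(y.std(), abs(hypothesized) * x.std())
    if resid.std() <= 1e-10 * scale or axis.std() <= 1e-10 * scale:
        # data fall (to numerical precision) on the hypothesized line
        return 1.0
    r = float(np.corrcoef(resid, axis)[0, 1])
    n = fit.n
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def slope_difference(fit1: SMAFit, fit2: SMAFit) -> float:
    """Two-sided p for equality of two SMA slopes (asymptotic z-test on
    log slope magnitudes, Var(log beta) = (1 - r^2)/(n - 2))."""
    v1 = (1.0 - fit1.r2) / (fit1.n - 2)
    v2 = (1.0 - fit2.r2) / (fit2.n - 2)
    z = (math.log(abs(fit1.slope)) - math.log(abs(fit2.slope))) / math.sqrt(v1 + v2)
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Logistic growth-curve fitting


@dataclass
class SigmoidFit:
    """3-parameter logistic fit m(t) = K / (1 + exp(-r (t - t0)))."""

    K: float
    t0: float
    r: float
    rss: float

    @property
    def mass_at_inflection(self) -> float:
        return self.K / 2.0


def _logistic(t, K, t0, r):
    return K / (1.0 + np.exp(-r * (t - t0)))


def fit_sigmoid_growth(times: Sequence[float], masses: Sequence[float]) -> SigmoidFit:
    """Fit a logistic growth trajectory; the inflection point t0 is the age
    of maximal daily growth and K/2 the vegetative dry mass at inflection."""
    t = np.asarray(times, dtype=float)
    m = np.asarray(masses, dtype=float)
    ok = np.isfinite(t) & np.isfinite(m)
    t, m = t[ok], m[ok]
    if len(t) < 5:
        raise ValueError("need >= 5 time points")
    K0 = max(m.max(), 1e-9)
    t00 = float(t[np.argmin(np.abs(m - K0 / 2))])
    span = t.max() - t.min()
    starts = [
        (K0, t00, 4.0 / max(span, 1e-9)),
        (1.05 * K0, float(np.median(t)), 8.0 / max(span, 1e-9)),
        (1.2 * K0, t00, 1.0 / max(span, 1e-9)),
    ]
    last_err = None
    best = None
    for p0 in starts:
        try:
            popt, _ = optimize.curve_fit(_logistic, t, m, p0=p0, maxfev=20000)
        except RuntimeError as err:
            last_err = err
            continue
        if popt[0] <= 0 or popt[2] <= 0:
            continue
        resid = m - _logistic(t, *popt)
        rss = float(resid @ resid)
        if best is None or rss < best.rss:
            best = SigmoidFit(K=float(popt[0]), t0=float(popt[1]), r=float(popt[2]), rss=rss)
    if best is None:
        raise FitError(f"logistic growth fit failed to converge: {last_err}")
    return best


# ---------------------------------------------------------------------------
# Model persistence


def save_model(model: AllometricModel, path) -> None:
    Path(path).write_text(json.dumps(asdict(model), indent=2))


def load_model(path) -> AllometricModel:
    data = json.loads(Path(path).read_text())
    data["ci95"] = {k: tuple(v) for k, v in data["ci95"].items()}
    return AllometricModel(**data)
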