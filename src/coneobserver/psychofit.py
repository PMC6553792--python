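"""Weibull psychometric fits, contrast thresholds, and factor summaries.

Accuracy versus contrast is summarized by the Weibull form

    y(x) = 1 - (1 - g) * exp(-(k x / t)^beta),
    k = (-log((1 - alpha) / (1 - g)))^(1/beta),

with chance level g = 0.5 (2-AFC), slope beta fixed at 3, and threshold t
defined so that y(t) = alpha = 0.5^(1/3) ~= 0.7937 exactly. Thresholds from
sweeps over a biological factor are then summarized by a quadratic
(L-cone probability), linear (defocus in diopters) or log-linear
(cone density) least-squares fit, with r^2 the squared Pearson correlation
between fitted and observed thresholds; inverting those fits yields the
factor change required for a given threshold change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

ALPHA_2AFC = 0.5 ** (1.0 / 3.0)  # ~0.7937, criterion performance at threshold


def weibull_k(beta: float = 3.0, g: float = 0.5, alpha: float = ALPHA_2AFC) -> float:
    """Constant k making y(t) = alpha."""
    return (-np.log((1.0 - alpha) / (1.0 - g))) ** (1.0 / beta)


def weibull(x, t: float, beta: float = 3.0, g: float = 0.5, alpha: float = ALPHA_2AFC):
    """Weibull proportion correct at contrast(s) x for threshold t."""
    if t <= 0:
        raise ValueError("threshold must be positive")
    x = np.asarray(x, dtype=float)
    k = weibull_k(beta, g, alpha)
    return 1.0 - (1.0 - g) * np.exp(-((k * x / t) ** beta))


@dataclass
class PsychometricFit:
    """Fitted Weibull parameters and provenance data."""

    t: float  # contrast threshold (fraction)
    beta: float
    g: float
    alpha: float
    x: np.ndarray
    y: np.ndarray
    residuals: np.ndarray
    identifiable: bool = True

    @property
    def k(self) -> float:
        return weibull_k(self.beta, self.g, self.alpha)

    @property
    def threshold_percent(self) -> float:
        """Threshold in percent contrast (the units used in all tables)."""
        return 100.0 * self.t


def fit_threshold(
    contrasts,
    accuracies,
    beta: float = 3.0,
    g: float = 0.5,
    alpha: float = ALPHA_2AFC,
    loss: str = "least_squares",
    n_per_level: int | None = None,
) -> PsychometricFit:
    """Fit the Weibull threshold t to mean accuracy per contrast level.

    beta and g are fixed; only t is free. Default loss is unweighted least
    squares on mean accuracies; ``loss='binomial'`` maximizes the binomial
    likelihood instead (requires ``n_per_level``). The optimizer multi-starts
    from 3 log-spaced initial values with t bounded in [1e-4, 1].

    Accuracies indistinguishable from chance are flagged non-identifiable
    (``identifiable=False``, t = nan) rather than returning a number.
    """
    x = np.asarray(contrasts, dtype=float)
    y = np.asarray(accuracies, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 contrast levels")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("accuracies must lie in [0, 1]")
    mask = x > 0
    x, y = x[mask], y[mask]

    # not identifiable if performance never rises meaningfully above chance
    if np.all(y < g + 0.075):
        return PsychometricFit(
            t=float("nan"), beta=beta, g=g, alpha=alpha, x=x, y=y,
            residuals=y - g, identifiable=False,
        )

    def resid(logt, ret_pred=False):
        pred = weibull(x, float(np.exp(np.asarray(logt).ravel()[0])), beta, g, alpha)
        if loss == "binomial":
            n = n_per_level or 1
            eps = 0.5 / max(n, 2)
            p = np.clip(pred, eps, 1 - eps)
            # deviance residuals (signed sqrt of per-level deviance)
            ll = y * np.log(p) + (1 - y) * np.log(1 - p)
            ll_sat = np.where(
                (y > 0) & (y < 1), y * np.log(y + 1e-12) + (1 - y) * np.log(1 - y + 1e-12), 0.0
            )
            d = 2 * n * (ll_sat - ll)
            r = np.sign(y - p) * np.sqrt(np.maximum(d, 0.0))
        else:
            r = y - pred
        return (pred, r) if ret_pred else r

    best = None
    for t0 in np.geomspace(3e-3, 0.3, 3):
        sol = least_squares(
            resid, x0=[np.log(t0)], bounds=([np.log(1e-4)], [np.log(1.0)])
        )
        if best is None or sol.cost < best.cost:
            best = sol
    t_hat = float(np.exp(best.x[0]))
    pred, r = resid(best.x, ret_pred=True)
    return PsychometricFit(
        t=t_hat, beta=beta, g=g, alpha=alpha, x=x, y=y, residuals=y - pred
    )


@dataclass
class FactorFit:
    """Least-squares summary of threshold versus a biological factor."""

    model_form: str  # 'linear' | 'quadratic' | 'log-linear'
    coefficients: np.ndarray  # highest power first (numpy polynomial order)
    r_squared: float
    factor_values: np.ndarray
    thresholds: np.ndarray

    def predict(self, factor):
        f = np.asarray(factor, dtype=float)
        xx = np.log10(f) if self.model_form == "log-linear" else f
        return np.polyval(self.coefficients, xx)

    @property
    def slope(self) -> float:
        """Linear coefficient (threshold units per factor unit or per decade)."""
        return float(self.coefficients[-2])


def fit_factor_curve(factor_values, thresholds, model_form: str = "linear") -> FactorFit:
    """Fit thresholds against a factor with the stated functional form.

    'linear' and 'log-linear' are degree-1 polynomials (the latter in
    log10 of the factor, e.g. cone density); 'quadratic' is degree 2
    (e.g. L-cone probability). r^2 is the squared Pearson correlation of
    fitted versus observed thresholds.
    """
    f = np.asarray(factor_values, dtype=float)
    th = np.asarray(thresholds, dtype=float)
    if model_form not in ("linear", "quadratic", "log-linear"):
        raise ValueError(f"unknown model form {model_form!r}")
    deg = 2 if model_form == "quadratic" else 1
    if len(f) < deg + 1:
        raise ValueError("fewer points than fit parameters")
    x = np.log10(f) if model_form == "log-linear" else f
    coef = np.polyfit(x, th, deg)
    pred = np.polyval(coef, x)
    if np.allclose(th, th[0]):
        r2 = 1.0 if np.allclose(pred, th) else 0.0
    else:
        r2 = float(np.corrcoef(pred, th)[0, 1] ** 2)
    return FactorFit(
        model_form=model_form, coefficients=coef, r_squared=r2,
        factor_values=f, thresholds=th,
    )


def required_factor_change(fit: FactorFit, delta_threshold_pp: float) -> float:
    """Factor change producing a given threshold change (percentage points).

    * linear: returns the factor increment (e.g. diopters of defocus).
    * log-linear: returns the *fold change* of the factor (e.g. cone
      density) per ``delta_threshold_pp``; a fold change of 1 means none.
    * quadratic fits are not invertible over their whole range and are
      rejected.

    Thresholds in the fit are expected in percent-contrast units.
    """
    if fit.model_form == "quadratic":
        raise ValueError("quadratic fits are non-monotone; cannot invert")
    slope = fit.slope
    if slope == 0:
        raise ValueError("flat fit: threshold does not depend on the factor")
    if fit.model_form == "linear":
        return delta_threshold_pp / slope
    # log-linear: delta log10(factor) = delta_t / slope -> fold change
    return float(10.0 ** abs(delta_threshold_pp / slope))


def fit_summary_records(fits: dict[str, PsychometricFit]) -> list[dict]:
    """JSON-ready records (one per condition) of Weibull fit results."""
    out = []
    for name, f in fits.items():
        out.append(
            {
                "condition": name,
                "threshold_percent": None if not f.identifiable else round(f.threshold_percent, 4),
                "beta": f.beta,
                "g": f.g,
                "alpha": round(f.alpha, 6),
                "identifiable": f.identifiable,
            }
        )
    return out
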