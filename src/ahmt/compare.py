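"""Deming errors-in-variables regression for method comparison.

When two measurement procedures are compared level by level, both axes
carry error, so ordinary least squares (which attributes all error to y)
biases the slope.  Deming regression minimises

    sum_i [ (y_i - yhat_i)**2 + delta * (x_i - xhat_i)**2 ]

over the line and the fitted x-positions, where

    delta = var(error of y) / var(error of x)

is the ratio of the two procedures' error variances.  The slope has the
closed form

    a = [ (s_yy - delta*s_xx) + sqrt((s_yy - delta*s_xx)**2
          + 4*delta*s_xy**2) ] / (2*s_xy)

with s_xx, s_yy, s_xy the sample (co)variances, and b = mean(y) - a*mean(x).
Standard errors are estimated by leave-one-out jackknife.  Convention used
throughout: the automated procedure is y, the comparison (manual) procedure
is x, and delta is y-to-x.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "DemingFit",
    "deming_lambda",
    "deming_fit",
    "compare_modes",
    "DemingRegression",
]


@dataclass(frozen=True)
class DemingFit:
    """Errors-in-variables line y = slope·x + intercept with jackknife SEs."""

    slope: float
    intercept: float
    delta: float
    se_slope: float
    se_intercept: float
    n: int

    def slope_ci(self, confidence: float = 0.95) -> tuple[float, float]:
        """Jackknife confidence interval for the slope (t, n-1 dof)."""
        tcrit = stats.t.ppf(0.5 + confidence / 2.0, self.n - 1)
        return self.slope - tcrit * self.se_slope, self.slope + tcrit * self.se_slope


def deming_lambda(sd_x: float, sd_y: float) -> float:
    """Error-variance ratio delta = sd_y² / sd_x² (y-to-x)."""
    if sd_x <= 0 or sd_y <= 0:
        raise ValueError("standard deviations must be positive")
    return (sd_y / sd_x) ** 2


def _deming_ab(x: np.ndarray, y: np.ndarray, delta: float) -> tuple[float, float]:
    xbar, ybar = x.mean(), y.mean()
    sxx = np.mean((x - xbar) ** 2)
    syy = np.mean((y - ybar) ** 2)
    sxy = np.mean((x - xbar) * (y - ybar))
    if sxy == 0:
        if np.isclose(syy, delta * sxx):
            raise ValueError("orientation-ambiguous data: s_xy = 0 with s_yy = delta*s_xx")
        raise ValueError("s_xy = 0: no unique Deming line orientation")
    d = syy - delta * sxx
    a = (d + np.sqrt(d * d + 4.0 * delta * sxy * sxy)) / (2.0 * sxy)
    return float(a), float(ybar - a * xbar)


def deming_fit(
    x: Sequence[float], y: Sequence[float], delta: float = 1.0
) -> DemingFit:
    """Fit the Deming line to paired observations.

    ``delta`` is the y-to-x error-variance ratio; 1 gives orthogonal
    (major-axis) regression.  Requires at least 3 pairs with non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if delta <= 0:
        raise ValueError("delta must be positive")
    if np.all(x == x[0]):
        raise ValueError("x values must not all be equal")

    a, b = _deming_ab(x, y, delta)

    # Leave-one-out jackknife for the standard errors.
    keep = np.ones(n, dtype=bool)
    slopes = np.empty(n)
    intercepts = np.empty(n)
    for i in range(n):
        keep[i] = False
        slopes[i], intercepts[i] = _deming_ab(x[keep], y[keep], delta)
        keep[i] = True
    se_a = np.sqrt((n - 1) / n * np.sum((slopes - slopes.mean()) ** 2))
    se_b = np.sqrt((n - 1) / n * np.sum((intercepts - intercepts.mean()) ** 2))

    return DemingFit(a, b, float(delta), float(se_a), float(se_b), int(n))


def compare_modes(
    conc_auto: Sequence[float],
    conc_manual: Sequence[float],
    delta: float = 1.0,
) -> DemingFit:
    """Deming fit of automated-mode concentrations (y) on manual ones (x).

    ``conc_auto`` and ``conc_manual`` are level-aligned back-calculated
    concentrations; perfect agreement between the two procedures gives
    slope 1 and intercept 0.
    """
    a = np.asarray(conc_auto, dtype=float)
    m = np.asarray(conc_manual, dtype=float)
    if a.size != m.size:
        raise ValueError(
            f"level mismatch: {a.size} automated vs {m.size} manual values"
        )
    return deming_fit(m, a, delta=delta)


class DemingRegression(RegressorMixin, BaseEstimator):
    """Deming regression as a scikit-learn style estimator.

    Fitted attributes: ``slope_``, ``intercept_``, ``se_slope_``,
    ``se_intercept_``, ``n_``.

    Parameters
    ----------
    delta : float, default 1.0
        Ratio of y-error variance to x-error variance.
    """

    def __init__(self, delta: float = 1.0):
        self.delta = delta

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        fit = deming_fit(x, y, delta=self.delta)
        self.slope_ = fit.slope
        self.intercept_ = fit.intercept
        self.se_slope_ = fit.se_slope
        self.se_intercept_ = fit.se_intercept
        self.n_ = fit.n
        self.fit_ = fit
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * x + self.intercept_
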