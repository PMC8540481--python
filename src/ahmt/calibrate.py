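"""Signal processing and internal-standard calibration statistics.

The analytical signal of an analyte is the ratio of time-corrected peak
areas (TCPA = area / migration time) between the analyte and the internal
standard:

    y = (A_analyte / t_analyte) / (A_IS / t_IS)

TCPA removes the velocity dependence of CE peak areas, and the IS ratio
removes run-to-run injection and drift variability.  Calibration follows
the bioanalytical convention for a wide concentration range:

1. integrate peaks and form replicate-level (concentration, signal) points;
2. screen outliers on the standardized residuals of an unweighted line
   through all replicate points (single pass, default threshold 2);
3. average the surviving replicates per level;
4. fit a straight line by weighted least squares with weights w = 1/x,
   which equalises relative rather than absolute errors.

Concentrations of unknowns are then back-calculated as x = (y - b) / a.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .simulate import AnalyteModel, Electropherogram

__all__ = [
    "PeakMeasurement",
    "SignalPoint",
    "CalibrationFit",
    "MissingPeakError",
    "DegenerateCalibrationError",
    "integrate_peaks",
    "tcpa_signal",
    "reject_outliers",
    "fit_weighted",
    "back_calculate",
    "relative_error",
    "CalibrationCurve",
]


class MissingPeakError(ValueError):
    """No peak found above the detection floor in an analyte's window."""


class DegenerateCalibrationError(ValueError):
    """Outlier screening rejected every point."""


@dataclass(frozen=True)
class PeakMeasurement:
    """An integrated peak: apex migration time (min) and area (AU·min)."""

    analyte: str
    migration_time_min: float
    area: float

    @property
    def tcpa(self) -> float:
        """Time-corrected peak area, AU."""
        return self.area / self.migration_time_min


@dataclass(frozen=True)
class SignalPoint:
    """One replicate-level calibration point: (concentration, IS-ratio signal)."""

    x: float
    y: float
    replicate: int = 0
    outlier: bool = False


@dataclass(frozen=True)
class CalibrationFit:
    """Weighted straight-line calibration: y = slope·x + intercept."""

    slope: float
    intercept: float
    r_squared: float
    weight_scheme: str
    n_used: int
    n_rejected: int


def _apex(t: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Apex position and height, parabola-refined around sample ``i``."""
    if 0 < i < len(y) - 1:
        y0, y1, y2 = y[i - 1], y[i], y[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:  # concave triple, safe to interpolate
            shift = 0.5 * (y0 - y2) / denom
            shift = float(np.clip(shift, -0.5, 0.5))
            dt = t[i + 1] - t[i]
            return t[i] + shift * dt, y1 - 0.25 * (y0 - y2) * shift
    return float(t[i]), float(y[i])


def integrate_peaks(
    trace: Electropherogram,
    analytes: Sequence[AnalyteModel],
    search_window: float = 0.15,
    integration_half_width_sigmas: float = 5.0,
    min_height_au: float = 1e-6,
) -> list[PeakMeasurement]:
    """Baseline-subtracted trapezoidal peak integration.

    For each analyte the apex is located within ±``search_window``
    (fractional) of its nominal migration time, refined by parabolic
    interpolation, and the peak integrated over ±5σ around the apex.  The
    baseline is the trace median (peaks are narrow, so the median sits on
    the baseline).  Analytes whose window holds no signal above the
    detection floor are reported together in a :class:`MissingPeakError`.
    """
    t = np.asarray(trace.time_min, dtype=float)
    y = np.asarray(trace.absorbance, dtype=float)
    baseline = float(np.median(y))
    noise_sd = 1.4826 * float(np.median(np.abs(y - baseline)))
    floor = baseline + max(5.0 * noise_sd, min_height_au)

    peaks, missing = [], []
    for a in analytes:
        lo = a.migration_time_min * (1.0 - search_window)
        hi = a.migration_time_min * (1.0 + search_window)
        sel = (t >= lo) & (t <= hi)
        if not sel.any():
            raise ValueError(
                f"window for {a.name} ({lo:.2f}-{hi:.2f} min) outside trace range"
            )
        idx = np.flatnonzero(sel)
        i = idx[int(np.argmax(y[idx]))]
        if y[i] < floor:
            missing.append(a.name)
            continue
        apex_t, _ = _apex(t, y, int(i))
        half = integration_half_width_sigmas * a.peak_width_sigma_min
        win = (t >= apex_t - half) & (t <= apex_t + half)
        area = float(np.trapezoid(y[win] - baseline, t[win]))
        peaks.append(PeakMeasurement(a.name, apex_t, area))
    if missing:
        raise MissingPeakError(
            "no peak above the detection floor for: " + ", ".join(missing)
        )
    return peaks


def tcpa_signal(
    peaks: Sequence[PeakMeasurement], is_label: str = "procaine"
) -> dict[str, float]:
    """Analyte signals as TCPA ratios against the internal standard."""
    by_name = {p.analyte: p for p in peaks}
    if is_label not in by_name:
        raise ValueError(f"internal standard {is_label!r} missing from peaks")
    is_tcpa = by_name[is_label].tcpa
    if is_tcpa <= 0:
        raise ValueError("internal-standard TCPA must be positive")
    return {
        name: p.tcpa / is_tcpa for name, p in by_name.items() if name != is_label
    }


def reject_outliers(
    points: Sequence[SignalPoint], threshold: float = 2.0
) -> list[SignalPoint]:
    """Single-pass outlier screen on standardized residuals.

    An unweighted line is fitted through *all* replicate points; points
    whose residual exceeds ``threshold`` residual standard deviations are
    flagged.  Exactly collinear data produce no flags.  Raises
    :class:`DegenerateCalibrationError` if everything is flagged.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points for residual screening")
    x = np.array([p.x for p in points])
    y = np.array([p.y for p in points])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    dof = len(points) - 2
    s = np.sqrt(np.sum(resid**2) / dof) if dof > 0 else 0.0
    # residuals at float rounding level mean exactly collinear data
    if s <= 1e-10 * max(1.0, float(np.max(np.abs(y)))):
        s = 0.0
    if s == 0 or not np.isfinite(threshold):
        flags = np.zeros(len(points), dtype=bool)
    else:
        flags = np.abs(resid) > threshold * s
    if flags.all():
        raise DegenerateCalibrationError("residual screening flagged every point")
    return [replace(p, outlier=bool(f)) for p, f in zip(points, flags)]


def _weights(x: np.ndarray, scheme: "str | Callable[[np.ndarray], np.ndarray]"):
    if callable(scheme):
        return np.asarray(scheme(x), dtype=float)
    if scheme in ("1/x", "1/x one"):
        if np.any(x <= 0):
            raise ValueError("w = 1/x requires strictly positive concentrations")
        return 1.0 / x
    if scheme in ("1", "none", "unweighted"):
        return np.ones_like(x)
    raise ValueError(f"unknown weight scheme {scheme!r}")


def fit_weighted(
    x: Sequence[float],
    y: Sequence[float],
    weight_scheme: "str | Callable" = "1/x",
    n_rejected: int = 0,
) -> CalibrationFit:
    """Weighted least-squares line through level-averaged points.

    Defaults to the bioanalytical w = 1/x weighting; r² is the coefficient
    of determination of the weighted model (weighted residual and total
    sums of squares).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct concentration levels")
    w = _weights(x, weight_scheme)
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    intercept, slope = res.params
    scheme_name = weight_scheme if isinstance(weight_scheme, str) else "callable"
    return CalibrationFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(res.rsquared),
        weight_scheme=scheme_name,
        n_used=int(x.size),
        n_rejected=int(n_rejected),
    )


def back_calculate(fit: CalibrationFit, y: float) -> float:
    """Invert the calibration line: concentration producing signal ``y``."""
    if fit.slope == 0:
        raise ZeroDivisionError("cannot back-calculate with zero slope")
    return (y - fit.intercept) / fit.slope


def relative_error(fit: CalibrationFit, x_true: float, y: float) -> float:
    """Signed relative error of the back-calculated concentration."""
    if x_true == 0:
        raise ValueError("x_true must be non-zero")
    return (back_calculate(fit, y) - x_true) / x_true


class CalibrationCurve(RegressorMixin, BaseEstimator):
    """Full calibration pipeline as a scikit-learn style estimator.

    ``fit(x, y)`` takes replicate-level points, screens outliers on
    standardized residuals, averages replicates per concentration level and
    fits the weighted line.  Fitted attributes: ``slope_``, ``intercept_``,
    ``r_squared_``, ``n_used_``, ``n_rejected_``, ``outlier_mask_``.

    Parameters
    ----------
    weight_scheme : str or callable, default ``"1/x"``
        Weight as a function of concentration.
    outlier_threshold : float, default 2.0
        Standardized-residual cut; ``numpy.inf`` disables screening.
    """

    def __init__(self, weight_scheme="1/x", outlier_threshold: float = 2.0):
        self.weight_scheme = weight_scheme
        self.outlier_threshold = outlier_threshold

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        points = [SignalPoint(xi, yi, replicate=i) for i, (xi, yi) in enumerate(zip(x, y))]
        screened = reject_outliers(points, threshold=self.outlier_threshold)
        self.outlier_mask_ = np.array([p.outlier for p in screened])
        kept = [p for p in screened if not p.outlier]

        levels: dict[float, list[float]] = {}
        for p in kept:
            levels.setdefault(p.x, []).append(p.y)
        xm = np.array(sorted(levels))
        ym = np.array([np.mean(levels[xi]) for xi in xm])

        fit = fit_weighted(
            xm, ym, weight_scheme=self.weight_scheme,
            n_rejected=int(self.outlier_mask_.sum()),
        )
        self.slope_ = fit.slope
        self.intercept_ = fit.intercept
        self.r_squared_ = fit.r_squared
        self.n_used_ = len(kept)
        self.n_rejected_ = fit.n_rejected
        self.fit_ = fit
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * x + self.intercept_

    def inverse_predict(self, y):
        """Back-calculate concentrations from signals."""
        y = np.asarray(y, dtype=float).reshape(-1)
        return (y - self.intercept_) / self.slope_
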