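import numpy as np
import pytest
from hypothesis import given, seed, settings
from hypothesis import strategies as st
from scipy import optimize

from ahmt import profiles
from ahmt.calibrate import (
    CalibrationCurve,
    CalibrationFit,
    DegenerateCalibrationError,
    MissingPeakError,
    PeakMeasurement,
    SignalPoint,
    back_calculate,
    fit_weighted,
    integrate_peaks,
    reject_outliers,
    relative_error,
    tcpa_signal,
)
from ahmt.mixture import Solution
from ahmt.simulate import NoiseModel, simulate_run, Electropherogram

ANALYTES = profiles.DEFAULT_ANALYTES
QUIET = NoiseModel(area_cv=0.0, migration_drift_cv=0.0, baseline_sd=0.0)


def _level(c: float) -> Solution:
    return Solution(
        f"c{c:g}",
        {"prilocaine": c, "bupivacaine": c, "procaine": 100.0},
        internal_standard="procaine",
    )


# --- peak integration -------------------------------------------------


def test_noise_free_gaussians_integrate_within_a_tenth_percent():
    run = simulate_run(_level(50.0), ANALYTES, QUIET)
    peaks = {p.analyte: p for p in integrate_peaks(run, ANALYTES)}
    for a in ANALYTES:
        conc = 100.0 if a.name == "procaine" else 50.0
        expected = a.response_factor * conc * a.migration_time_min
        assert peaks[a.name].area == pytest.approx(expected, rel=1e-3)
        assert peaks[a.name].migration_time_min == pytest.approx(
            a.migration_time_min, rel=1e-4
        )


def test_flat_trace_reports_all_analytes_missing():
    blank = Solution("blank", {}, internal_standard=None)
    run = simulate_run(blank, ANALYTES, QUIET)
    with pytest.raises(MissingPeakError) as err:
        integrate_peaks(run, ANALYTES)
    for a in ANALYTES:
        assert a.name in str(err.value)


def test_integration_matches_generator_manifest():
    run = simulate_run(
        _level(25.0), ANALYTES, profiles.DEFAULT_NOISE,
        rng=np.random.default_rng(42),
    )
    peaks = {p.analyte: p for p in integrate_peaks(run, ANALYTES)}
    for name, true_area in run.metadata["true_areas"].items():
        assert peaks[name].area == pytest.approx(true_area, rel=5e-3)


# --- TCPA signal ------------------------------------------------------


def test_tcpa_ratio_of_equal_tcpas_is_one():
    peaks = [
        PeakMeasurement("procaine", 1.0, 1.0),
        PeakMeasurement("prilocaine", 2.0, 2.0),  # same TCPA as the IS
    ]
    assert tcpa_signal(peaks)["prilocaine"] == pytest.approx(1.0)


def test_tcpa_ratio_invariant_under_velocity_scaling():
    base = [
        PeakMeasurement("procaine", 1.6, 0.016),
        PeakMeasurement("prilocaine", 2.1, 0.05),
    ]
    scaled = [
        PeakMeasurement(p.analyte, p.migration_time_min * 1.3, p.area * 1.3)
        for p in base
    ]
    assert tcpa_signal(scaled)["prilocaine"] == pytest.approx(
        tcpa_signal(base)["prilocaine"], rel=1e-12
    )


def test_missing_internal_standard_is_an_error():
    with pytest.raises(ValueError, match="procaine"):
        tcpa_signal([PeakMeasurement("prilocaine", 2.1, 0.05)])


# --- outlier rejection ------------------------------------------------


def test_collinear_points_never_flagged():
    pts = [SignalPoint(x, 0.02 * x + 0.1) for x in (1.0, 2.0, 3.0, 4.0)]
    assert not any(p.outlier for p in reject_outliers(pts, threshold=0.5))


def test_single_gross_outlier_flagged():
    rng = np.random.default_rng(0)
    x = np.repeat([6.25, 12.5, 25, 37.5, 50, 75, 100], 3)
    y = 0.02 * x + rng.normal(0, 1e-4, x.size)
    y[10] += 0.5  # gross displacement
    screened = reject_outliers([SignalPoint(a, b) for a, b in zip(x, y)])
    flags = [p.outlier for p in screened]
    assert flags[10] and sum(flags) == 1


def test_infinite_threshold_flags_nothing():
    rng = np.random.default_rng(1)
    pts = [SignalPoint(x, 0.02 * x + rng.normal(0, 0.01)) for x in range(1, 10)]
    assert not any(p.outlier for p in reject_outliers(pts, threshold=np.inf))


def test_too_few_points_rejected():
    with pytest.raises(ValueError):
        reject_outliers([SignalPoint(1, 1), SignalPoint(2, 2)])


# --- weighted fit -----------------------------------------------------


def test_exact_line_recovered():
    x = np.array([6.25, 12.5, 25, 37.5, 50, 75, 100])
    fit = fit_weighted(x, 0.02 * x - 0.01)
    assert fit.slope == pytest.approx(0.02, rel=1e-12)
    assert fit.intercept == pytest.approx(-0.01, rel=1e-9)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_nonpositive_concentration_rejected():
    with pytest.raises(ValueError, match="positive"):
        fit_weighted([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])


def _wls_objective(params, x, y, w):
    a, b = params
    r = y - a * x - b
    return np.sum(w * r**2), np.array([-2 * np.sum(w * r * x), -2 * np.sum(w * r)])


@seed(20211016)
@settings(max_examples=100, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_weighted_fit_matches_brute_force_minimiser(data_seed):
    """The closed-form weighted fit minimises the 1/x-weighted sum of
    squares: agreement with a numerical optimiser to 1e-8."""
    rng = np.random.default_rng(data_seed)
    n = rng.integers(4, 12)
    x = np.sort(rng.uniform(1.0, 100.0, n))
    y = rng.uniform(0.01, 0.03) * x + rng.normal(0, 0.05, n)
    fit = fit_weighted(x, y)
    res = optimize.minimize(
        _wls_objective, x0=np.polyfit(x, y, 1), args=(x, y, 1.0 / x),
        jac=True, method="BFGS", options={"gtol": 1e-14},
    )
    assert fit.slope == pytest.approx(res.x[0], abs=1e-8)
    assert fit.intercept == pytest.approx(res.x[1], abs=1e-8)


def test_duplicate_levels_averaged_before_weighting():
    """Fitting replicate points through the estimator equals fitting their
    per-level means directly."""
    rng = np.random.default_rng(3)
    levels = np.array([6.25, 12.5, 25, 37.5, 50, 75, 100])
    x = np.repeat(levels, 3)
    y = 0.02 * x + rng.normal(0, 1e-4, x.size)
    curve = CalibrationCurve(outlier_threshold=np.inf).fit(x, y)
    means = np.array([y[x == L].mean() for L in levels])
    direct = fit_weighted(levels, means)
    assert curve.slope_ == pytest.approx(direct.slope, rel=1e-12)
    assert curve.intercept_ == pytest.approx(direct.intercept, rel=1e-9)


def test_r_squared_below_one_with_nonzero_residuals():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.0, 2.1, 2.9, 4.2])
    fit = fit_weighted(x, y)
    assert 0 <= fit.r_squared < 1


# --- back-calculation -------------------------------------------------


def test_back_calculation_inverts_the_line():
    fit = CalibrationFit(0.02, -0.01, 1.0, "1/x", 7, 0)
    assert back_calculate(fit, 0.99) == pytest.approx(50.0)
    assert relative_error(fit, 50.0, 0.99) == pytest.approx(0.0, abs=1e-12)
    y = 0.02 * 33.0 - 0.01
    assert back_calculate(fit, y) == pytest.approx(33.0, rel=1e-12)


def test_zero_slope_back_calculation_rejected():
    fit = CalibrationFit(0.0, 0.0, 0.0, "1/x", 3, 0)
    with pytest.raises(ZeroDivisionError):
        back_calculate(fit, 1.0)


# --- end-to-end parameter recovery ------------------------------------


def test_noise_free_series_recovers_generator_slope_to_1e6():
    """A noise-free synthetic series gives back the generator's slope
    (response-factor ratio / IS concentration) and zero intercept."""
    levels = [6.25, 12.5, 25, 37.5, 50, 75, 100]
    x, y = [], []
    for c in levels:
        run = simulate_run(_level(c), ANALYTES, QUIET)
        signals = tcpa_signal(integrate_peaks(run, ANALYTES))
        x.append(c)
        y.append(signals["prilocaine"])
    fit = fit_weighted(np.array(x), np.array(y))
    rf = {a.name: a.response_factor for a in ANALYTES}
    true_slope = rf["prilocaine"] / (rf["procaine"] * 100.0)
    assert fit.slope == pytest.approx(true_slope, rel=1e-6)
    assert fit.intercept == pytest.approx(0.0, abs=1e-6 * true_slope * 100)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-9)


def test_estimator_sklearn_contract():
    from sklearn.base import clone

    curve = CalibrationCurve(outlier_threshold=3.0)
    assert clone(curve).get_params()["outlier_threshold"] == 3.0
    x = np.array([6.25, 12.5, 25, 37.5, 50, 75, 100])
    curve.fit(x, 0.02 * x - 0.01)
    np.testing.assert_allclose(curve.predict([50.0]), [0.99], rtol=1e-9)
    np.testing.assert_allclose(curve.inverse_predict([0.99]), [50.0], rtol=1e-9)
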