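# ahmt — automated in-instrument preparation of CE calibration solutions

Quantitative capillary-electrophoresis (CE) analysis needs a series of
calibration solutions, conventionally prepared by manual pipetting — slow,
operator-dependent and wasteful of standards. A CE instrument can instead
prepare them itself: its pressure system drives liquid through the
capillary, so a timed pressure application dispenses a controlled volume
into a collection vial. `ahmt` is a toolkit for planning, simulating and
statistically evaluating that preparation technique, aimed at CE method
developers and analytical chemists automating internal-standard
calibration.

## The model

Flow through the capillary is laminar, so delivered volume follows
Hagen–Poiseuille, V = ΔP·πr⁴/(8ηL)·t, and is proportional to the
pressure·time product p·t. Each level is constituted from a working
standard (WS, analytes + internal standard at 100 µg/mL) transfer and a
diluent (DBGE, internal standard only) transfer under a constant budget

    t_WS·p_WS + t_DBGE·p_DBGE = B,

which keeps the collected volume identical across levels; the target
concentration c fixes the split P_WS = B·c/c_stock. The scheduler realises
each product on the instrument's pressure/time grid (quantised pressures,
integer minutes, bounded transfer time), reporting any quantisation error
as an achieved-concentration shift.

Evaluation statistics follow bioanalytical practice: time-corrected peak
areas (TCPA = area / migration time) referenced to the internal standard,
single-pass outlier screening on standardized residuals, replicate
averaging, weighted least squares with w = 1/x, and Deming
errors-in-variables regression (slope closed form, jackknife standard
errors) for comparing automated against manual preparation. A synthetic
electropherogram generator with exactly known truth makes the whole chain
testable without instrument data.

## Worked example

Plan the six-level PCR-vial series (stock 100 µg/mL):

```
$ ahmt plan --vial pcr --out plan
 level  target_conc solution  t_min  p_psi  p_kpa  product  achieved_conc  rel_error
     0         6.25       WS   10.0    2.5  17.24     25.0           6.25        0.0
     0         6.25     DBGE   15.0   25.0 172.37    375.0           6.25        0.0
     1        12.50       WS   10.0    5.0  34.47     50.0          12.50        0.0
     1        12.50     DBGE   14.0   25.0 172.37    350.0          12.50        0.0
     2        25.00       WS   10.0   10.0  68.95    100.0          25.00        0.0
     2        25.00     DBGE   10.0   30.0 206.84    300.0          25.00        0.0
     3        37.50       WS   10.0   15.0 103.42    150.0          37.50        0.0
     3        37.50     DBGE   10.0   25.0 172.37    250.0          37.50        0.0
     4        50.00       WS   10.0   20.0 137.90    200.0          50.00        0.0
     4        50.00     DBGE   10.0   20.0 137.90    200.0          50.00        0.0
     5        75.00       WS   10.0   30.0 206.84    300.0          75.00        0.0
     5        75.00     DBGE   10.0   10.0  68.95    100.0          75.00        0.0
```

Each row is one transfer: e.g. the 6.25 µg/mL level takes 25 psi·min of WS
(10 min at 2.5 psi) and 375 psi·min of diluent — too much pressure for the
default 10 min, so the transfer is lengthened to 15 min at 25 psi. Every
product sums to the 400 psi·min budget, so all six vials collect the same
≈ 93.5 µL.

The full chain — plan, timed sequence, synthetic triplicate
electropherograms for an automated and a manual series, calibration and
Deming comparison:

```
$ ahmt run --seed 42 --out run1
Calibration series: 7 levels in pcr vials, mode R
Preparation time: 150.5 min
prilocaine: slope 0.0232, intercept -0.0022, r^2 0.9997 (1 outlier(s) rejected)
bupivacaine: slope 0.0123, intercept -0.0035, r^2 0.9998 (1 outlier(s) rejected)
prilocaine auto vs manual: slope 0.984 +/- 0.023, intercept 0.324 +/- 0.611
bupivacaine auto vs manual: slope 0.976 +/- 0.044, intercept 0.610 +/- 1.151
```

Preparation of the six diluted calibrators takes 150.5 min (~2.5 h) of
unattended instrument time. The calibration slopes recover the generator's
response-factor ratios (0.023 and 0.012 mL/µg) and the Deming slopes sit
within two standard errors of 1 — the two preparation modes are
statistically equivalent on this synthetic run.

The same is available as a library:

```python
from ahmt import RunConfig, run_end_to_end
report = run_end_to_end(RunConfig(vial="nano", seed=7), "outdir")
```

and the regression pieces (`CalibrationCurve`, `DemingRegression`) are
scikit-learn-style estimators usable on their own.

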