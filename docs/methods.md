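# Methods

## The preparation model

A capillary-electrophoresis (CE) instrument can prepare its own calibration
solutions: its pressure system drives liquid through the separation
capillary, so a timed pressure application dispenses a controlled volume
into a collection vial. Each calibration level is constituted from two
transfers — working standard (WS: both analytes and the internal standard
at the stock level, 100 µg/mL) and diluent (DBGE: 10-fold diluted
background electrolyte carrying only the internal standard at 100 µg/mL).

Flow through the capillary is laminar (Reynolds number « 1 at these
pressures and bore sizes), so delivered volume follows Hagen–Poiseuille:

    V = Q · t,    Q = ΔP · π r⁴ / (8 η L)

with r the inner radius, L the **total** capillary length (the effective,
inlet-to-detector length matters only for detection) and η the viscosity.
Assuming WS and DBGE have equal viscosity, volume is proportional to the
pressure·time product p·t, and the composition of a vial depends only on
the *ratio* of the two products — geometry and viscosity cancel. Holding

    t_WS·p_WS + t_DBGE·p_DBGE = B  (constant across levels)

therefore fixes the collected volume per vial, and the concentration target
fixes the split:

    P_WS = B · c_target / c_stock,   P_DBGE = B − P_WS.

The budget B is anchored by the symmetric 2-fold dilution level: both
transfers at the reference time and pressure, so B = 2·t_ref·p_ref
(400 psi·min for PCR vials at 10 min / 20 psi; 40 psi·min for nanoVials at
10 min / 2 psi).

## Realising products on the instrument grid

The instrument cannot execute arbitrary (t, p) pairs. The scheduler maps an
ideal product P onto the executable grid in three ordered rules:

1. **Quantise pressure at the default time.** p₀ = P / t_default; if p₀ is
   within [p_min, p_max], use t_default and round p₀ to the pressure
   quantum, half away from zero (3.75 → 3.8 psi at a 0.1 psi quantum). This
   is the only rule that can change the product; the schedule recomputes the
   achieved concentration and reports the relative dilution error.
2. **Lengthen the transfer when pressure would overshoot.** Take the
   smallest on-grid time above the default (up to t_max) for which P/t is
   both within range and an exact multiple of the pressure quantum — the
   product is preserved exactly. If no grid time qualifies, the level is
   reported infeasible by name rather than silently approximated; an
   exhaustive (t, p) grid enumeration in the tests confirms both the
   minimal-time choice and the feasibility verdict.
3. **Pin pressure at the minimum when it would undershoot**, shortening the
   time to P/p_min snapped to the time grid.

Defaults: time grid of 1 min up to 15 min with a 10 min default (the
shortest transfer with repeatable delivery, CV < 3%); pressure 2.5–30 psi
in 0.5 psi steps for PCR vials, 0.5–3.8 psi in 0.1 psi steps for nanoVials.
The 3.8 psi ceiling is the maximum the validated method used, not a
hardware limit. The pressure quanta are inferred from the printed settings
of the reference method; both are configurable. A target equal to the stock
yields a pass-through level (the undiluted WS used as top calibrator), not
a zero-duration transfer.

With these defaults the scheduler reproduces, from the constant-budget rule
alone, every time/pressure pair of the validated reference series for both
vial formats, including the three non-obvious cells: DBGE 15 min / 25 psi
at 6.25 µg/mL and 14 min / 25 psi at 12.5 µg/mL (rule 2), and WS
5 min / 0.5 psi plus DBGE 10 min / 3.8 psi at the lowest nanoVial level
(rules 3 and 1). The quantisation at that level makes the achieved
concentration 6.17 µg/mL rather than 6.25 (2.5/40.5 × 100); the schedule
reports it rather than hiding it.

## Sequence and accounting

A run is: initial rinse block (water 1.5 min, methanol 1 min, air-dry
1.5 min, all at 20 psi), WS fill (2 min), WS transfer to each vial, water
rinse (3 min) and DBGE fill (2 min), DBGE transfer to each vial, final
rinse block (water/methanol/air 1.5 min each), then a 1 min / 30 psi
air-bubbling mix per vial. Tip cleaning (dipping the capillary tip in
water between vials) has no instrument-timed duration and defaults to
0 min, configurable. For six PCR levels this totals 150.5 min
(6 + 60 + 5 + 69 + 4.5 + 6), the ~2.5 h figure for an unattended
preparation. Between-run separation steps are representable as
annotation-only events excluded from the preparation total. Reverse and
forward modes differ only in which tray holds the sources, so they share
the event multiset and duration.

Reagent accounting converts each pressurised liquid event through the flow
model; air (drying, mixing) is never counted as a consumed reagent. With
the default geometry (30.5 cm × 50 µm) and water at 0.89 mPa·s — the
ambient-tray viscosity assumption, exposed as configuration since the
instrument does not thermostat the trays — one PCR vial collects ≈ 93.5 µL
and one nanoVial ≈ 9.35 µL, consistent with the method's "about 100 µL"
and "down to 10 µL" scale claims.

## Synthetic electropherograms

The generator exists to give the statistics inputs with known truth, not to
model separations. Each analyte contributes a Gaussian peak; its area is
response_factor × concentration × (drifted) migration time, because a
slower analyte spends proportionally longer in the detector window — the
very effect time-corrected peak area (TCPA = area / migration time)
removes. Noise has three parts: multiplicative mean-one log-normal area
noise (default CV 2%, inside the method's < 3% repeatability criterion), a
per-run velocity factor shared by all peaks (default CV 1%), and additive
baseline noise (default 0.5 mAU). Migration times 1.6 / 2.1 / 2.6 min and
response factors 1.0 / 2.3 / 1.2 × 10⁻⁴ AU·mL/µg for procaine (the
internal standard) / prilocaine / bupivacaine are fixture choices giving
baseline-resolved peaks of realistic height and IS-ratio calibration slopes
of realistic magnitude (~0.023 and ~0.012 mL/µg); they are properties of
the generator, not measured values. Sampling is 10 Hz with 0.02 min peak
sigma, giving ≥ 2000 points per trace and trapezoidal integration accurate
to well under 0.1%.

What the generator deliberately omits: electroosmotic-flow variation beyond
a scalar drift, electromigration dispersion and peak asymmetry, stacking,
detector saturation, and baseline wander. Passing tests therefore
demonstrate the *statistical machinery* (TCPA/IS cancellation, weighting,
outlier screening, Deming comparison) under controlled conditions, not
performance on real detector data.

## Calibration statistics

Signals are y = TCPA_analyte / TCPA_IS, computed from baseline-subtracted
trapezoidal areas (baseline = trace median; apex refined by three-point
parabola; integration over ±5σ around the apex). The pipeline order
matches bioanalytical practice: screen outliers on the standardized
residuals of an unweighted line through all replicate points (single pass,
default threshold 2 — configurable, since the convention varies), average
surviving replicates per level, then fit weighted least squares with
w = 1/x, the standard weighting when calibration spans more than a decade
and relative rather than absolute error should be equalised. r² is the
weighted coefficient of determination. Back-calculation inverts the line,
x̂ = (y − b)/a.

Residual SDs at the floating-point rounding level are treated as exactly
collinear data (no outlier flags); rejecting every point raises a
degenerate-calibration error rather than returning an empty fit.

## Method comparison

Two preparation modes are compared by Deming errors-in-variables
regression of level-wise back-calculated concentrations, automated mode on
y and manual on x, with δ = (error variance of y)/(error variance of x)
estimated from the mode-wise mean replicate SDs. The slope is the standard
closed form in the sample (co)variances; tests verify it against direct
numerical minimisation of the errors-in-variables objective (with the
latent x-positions profiled out) and against the orthogonal-regression and
OLS limits at δ = 1, δ → ∞ and δ → 0. Standard errors use the
leave-one-out jackknife; analytic small-sample SEs exist under normality
assumptions, but the jackknife is assumption-light at the n ≈ 7 typical
here. Its 95% CIs undercover slightly at that n, which the acceptance
test acknowledges by checking coverage across independent synthetic pairs
rather than a single draw.

## Problem sizes and numerical choices

Schedulers and sequences are exact and instantaneous. Statistical
properties are exercised at the study's own scale — seven levels
(6.25–100 µg/mL) in triplicate — with 200 seeded repetitions for the
back-calculation accuracy check (the mid-range levels stay within 4% of
truth in ≥ 95% of repetitions), 100 random datasets for each
closed-form-vs-optimiser equivalence, and 30 independent mode pairs for
the Deming coverage check. Grid-snapping comparisons use a 10⁻⁹ relative
tolerance; mixing is mass-conservative to 10⁻¹²; all randomness flows
from explicit seeds through `numpy.random.default_rng`.

## Known limitations

* The viscosity/temperature of the tray liquids is assumed, not measured;
  absolute volumes scale inversely with η (compositions do not).
* The equal-viscosity assumption is hard-coded for composition; a
  WS/DBGE viscosity mismatch would bias the split in proportion to the
  mismatch.
* Rule 2 insists on exact grid products; targets whose products have no
  exact grid realisation are infeasible by design rather than approximated.
* The outlier-screening conditions in published practice vary; only the
  single-pass standardized-residual screen is implemented.
* Jackknife SEs, not analytic ones; see above.
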