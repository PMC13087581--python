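# Methods

## Scope and data model

`nephelofit` analyses liquid-culture growth assays recorded as per-well
time series on a 96-well plate. Input is a tidy CSV dialect
(`well,time_h,value` plus a layout table) rather than any instrument
vendor's export; times are elapsed hours rebased to the file's earliest
measurement, because every downstream quantity depends only on elapsed
time. Two signal kinds are supported: RNU from a plate nephelometer
sampling every 10 minutes, and OD600 from manual spectrophotometric
reads roughly twice a day. Both pass through the identical analysis
chain; only the simulator's defaults differ between the modes.

## Preprocessing chain

Applied per technical-replicate well, in this order:

1. **Blank correction** — subtract, per time point, the mean of the
   non-inoculated blank wells of the same growth medium. The mean of the
   triplicate blanks is used rather than a single matched well; blanks
   must share the sample's time grid to within half a sampling interval.
   Negative results are retained — clipping would bias the baseline, and
   the later clamping/rebasing steps subsume sign handling.
2. **Negative-control normalisation** — for wells grown on the test
   medium only, subtract the per-time mean of the empty-vector control
   strain's blank-corrected traces. Basal growth of the host strain is a
   nuisance signal on the selective medium but is the signal of interest
   elsewhere, so applying this step to other media is a warning no-op.
3. **Pre-minimum clamping** — find the curve's global minimum (first
   occurrence on ties) and set all earlier values to it. This removes
   early instrument transients before growth.
4. **Rebasing** — shift additively so the first value is exactly 1
   unit. The shift (not a rescale) preserves all pairwise differences,
   hence the empirical maximum-slope time; a division would distort
   blank-corrected values near zero.
5. **Savitzky–Golay smoothing** — order 2, window the smallest odd
   integer ≥ max(5, round(0.1·n)) (n = 1081 points → window 109; n = 14
   → window 5). The minimum trace length of 5 points follows from the
   smallest window. Terminal points are evaluated from the polynomial
   fitted in the one-sided end windows — no reflected or zero padding,
   so no data is fabricated where lag and plateau are read. Time grids
   may jitter up to 10% of the median step before the smoother refuses.
6. **Technical-replicate averaging** — pointwise mean within each
   (construct, medium, biological replicate) group. Averaging after
   smoothing follows the numbered order of the protocol this implements.
   When technical replicates are the desired statistical unit the
   averaging step can be skipped (`unit="tech"`).

Because smoothing follows rebasing, the first value of a finished curve
is exactly 1 only up to the smoother's re-estimate of the end point; on
noisy wells it moves by the order of the local noise.

## Logistic fit

The model is `N(t) = K/(1 + ((K−N0)/N0) e^{−rt})` with K, N0, r > 0.
For t ≥ 0 the denominator is bounded below by min(1, K/N0) > 0, so the
model is well defined over the whole feasible box. Fitting minimises the
sum of squared residuals with a trust-region reflective solver, box
lower bounds 1e-12 on all three parameters (the least transformation
that enforces positivity), ftol/xtol/gtol 1e-10 and at most 10⁴
evaluations; non-convergence is flagged, never silently discarded.

Initial values: K₀ and N0₀ are the curve's maximum and minimum, and
r₀ = ln((K₀−N0₀)/N0₀)/μ̂ with μ̂ the empirical maximum-slope time (the
midpoint of the steepest forward-difference interval, earliest on ties),
computed on the smoothed curve. Two degeneracies are handled:

* a non-positive minimum (possible after background subtraction plus
  smoother ringing at the clamp edge) cannot seed a positive model, so
  N0₀ falls back to the curve's smallest positive value. Without this
  fallback the optimiser can reach a degenerate step-function minimum
  (N0 at the bound, r in the hundreds) on noisy plates;
* when the rate expression is undefined ((K₀−N0₀)/N0₀ ≤ 1 or μ̂ ≤ 0),
  r₀ = 1/(time span) keeps the start in a sane rate regime.

Derived metrics: maximum-slope time μ = ln((K−N0)/N0)/r; maximum growth
rate rK/4; lag time from the classical tangent-at-inflection
construction, t_lag = μ − 2/r + 4N0/(rK), clipped at 0. When K ≤ 2N0
the inflection would lie at t ≤ 0; over observable times the slope is
then maximal at t = 0, so μ and the lag are reported as 0 with the
boundary case distinguishable via the fit's `has_interior_inflection`.
The lag formula is a design choice: the tangent construction is the
standard growth-curve definition and is fully determined by (K, N0, r).

Nephelometric curves can decline after a peak (see below); by default
the logistic is fitted through the full trace, with an optional
`truncate_at_peak` switch that drops points after the global maximum.

## Group comparison

Constructs are compared with a two-sided Mann–Whitney U test on a chosen
metric, one value per biological replicate (technical replicates having
been averaged upstream; a technical-unit option exists because small
assays sometimes pool them). Midranks handle ties;
U = min(U_a, U_b) (classical-table convention; the directional statistic
is recoverable as n_a·n_b − U). For tie-free data with n_a·n_b ≤ 400 the
p-value is exact: the null distribution of U over all C(n_a+n_b, n_a)
rank assignments is computed by the counting recurrence
f(i,j,u) = f(i−1,j,u−j) + f(i,j−1,u), and the one-tail probability
P(U ≤ u_obs) is doubled, capped at 1. Larger or tied samples use the
normal approximation with tie correction and a 0.5 continuity
correction. Samples with all values identical return p = 1 with a
degenerate flag.

The exact test is discrete: at n = 6 vs 6 the rejection region at
α = 0.05 is U ≤ 5 and the attained size is 38/924 ≈ 0.0411, not 0.05.
This conservatism is a property of every exact rank test at small n (the
next larger region already has size 60/924 ≈ 0.065) and should be kept
in mind when reading simulated rejection rates.

## Synthetic plates

The simulator generates the data structure the analysis assumes, with
exported per-well ground truth:

* each construct group grows logistically; N0 is derived from the
  group's nominal (K, r, μ) via N0 = K/(1+e^{rμ}), so the true
  maximum-slope time is exact by construction;
* biological replicates perturb r by a lognormal factor with coefficient
  of variation `r_bio_cv` (default 0.05 — a realistic batch-to-batch
  spread for independently grown cultures); technical replicates share
  the realised rate and differ only in noise. Putting the replicate
  effect on r keeps each replicate's true μ in closed form;
* the host strain's basal growth (the empty-vector control, default
  K = 3% of the largest sample K, r = 0.05 h⁻¹, μ = 60 h) is added to
  every transporter-group well and constitutes the control wells
  themselves, so the normalisation step removes a component that
  actually exists in the generative model;
* blanks are baseline plus noise (optional linear drift for robustness
  experiments); noise is zero-mean Gaussian with sd = noise_sd·K of the
  well's group (blanks use the largest group K as the shared instrument
  scale). Defaults: 0.02 (nephelometric), 0.04 (spectrophotometric,
  emulating manual handling);
* nephelometric mode multiplies the signal by
  1 + a·(N/K)·e^{−decay·max(0, t−t_onset)}, t_onset being the first time
  N ≥ onset·K (defaults a = 0.3, onset = 0.8, decay = 0.05 h⁻¹). This
  is a minimal phenomenological stand-in for multiple-scattering
  amplification in dense cultures — amplification grows with density,
  then relaxes — reproducing the characteristic peak → decline → plateau
  shape. It is not an optical model, and its default magnitudes are
  shape choices, not instrument claims;
* well positions are shuffled deterministically from the seed; identical
  config and seed give bit-identical datasets.

What the simulator does **not** emulate: evaporation and edge effects,
cross-well optical bleed, aggregation/clumping noise, nutrient-depletion
dynamics beyond the logistic closed form, or instrument gain changes
between runs. Passing tests therefore demonstrate correctness of the
analysis chain under the stated statistical structure, not robustness to
every artefact of real plates.

## Numerical behaviour worth knowing

* On a noiseless plate at the canonical conditions (K = 1000, N0 = 1,
  r = 0.1 h⁻¹, 10-minute sampling over 180 h) the full chain recovers
  the inflection ln(999)/0.1 ≈ 69.07 h to better than 0.001 h; the
  smoothing bias is negligible because a symmetric order-2
  Savitzky–Golay filter also reproduces cubics at the window centre.
* Under baseline noise that is large relative to N0 (e.g. sd = 2% of K
  with N0 = 1 unit), the clamp/rebase steps anchor the curve to the most
  extreme downward noise excursion (≈3σ over a thousand points),
  inflating fitted K and N0 by several percent and deflating r by more
  (~10–15% under those conditions). Maximum-slope time is essentially
  unaffected, because the rebasing shift preserves differences — which
  is why μ, not r, is the chain's robust readout. Fitting the logistic
  directly to the noisy signal (without clamp/rebase) keeps median K and
  r errors well under 1% at the same noise.
* With the peak artifact at amplitude 0.3, fitting through the peak
  biases μ̂ a few hours early (the amplified region pulls the rise), but
  the recovered μ stays within 10% of truth and the bias is common to
  groups measured under the same optics, so between-group offsets
  survive (a 5 h offset is detected with the correct sign in ≥95% of
  seeded runs at 2% noise, 3×3 replicates).
* Exact-test p-values at n = 3 vs 3 cannot go below 0.1; detecting
  differences at conventional α needs more biological replicates or the
  technical-replicate unit, which conflates within-culture variance with
  the biological question and is therefore not the default.

## Problem sizes

Tests and the acceptance script run on full-scale nephelometric grids
(1081 points per well, 12–30 wells per plate). The heavier simulations
use 100 seeded plates (offset detection), 10⁴ null draws (type-I
calibration) and 20 seeded plates (noise and artifact recovery); the
whole suite completes in a few minutes on one CPU.
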