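# Methods notes

This note records the scientific and numerical choices behind
`baleendo`, in the spirit of a model-description appendix: what is
assumed, what is tunable, what the simulator does and does not emulate,
and where the design was genuinely open.

## Coordinate and date conventions

Position along a plate is measured in cm from the gumline ("zero cm",
newest keratin), increasing toward the tip (oldest). The zero-cm point
is dated to the day before the whale was found dead unless an explicit
death date is supplied (e.g. back-dated from foetal length and carcass
condition). Dates carry day precision; years are 365.25 days and a
"month" in duration arithmetic is 365.25/12 ≈ 30.44 days, while
conception/birth month statements use calendar month-of-year
arithmetic. All modules share these conventions.

## Isotope chronology

- **Smoothing**: "4 nearest neighbours" is implemented as a centred
  5-point window (the sample plus two neighbours per side), shrinking
  symmetrically at the plate ends. The window is a config knob
  (`smoothing_window`, default 5, odd); the alternative reading (four
  per side, a 9-point window) can be selected.
- **Peak detection** is deterministic: interior local maxima ranked by
  descending smoothed height (ties broken toward the gumline), accepted
  greedily subject to a minimum separation (default 5 cm, chosen so a
  peak lies outside its neighbour's moving-average window). Plate ends
  are never peaks: a partial cycle edge is not evidence of an annual
  maximum.
- **Growth rates**: each inter-peak distance is one year of growth;
  the mean of the cycle rates is the plate's average BGR. Between
  consecutive peaks the timeline uses that cycle's rate; the partial
  cycles before the first and after the last peak use the mean rate.
  With fewer than two peaks (or no isotope series) the timeline falls
  back to a configured default BGR (default 20 cm/yr, the value assigned
  to young whales without isotope data in the source case study).
- Peaks are dated purely by back-calculation from the zero date; no
  calendar anchoring of peaks to a feeding season is attempted.

## Assay reduction

- The standard curve is a four-parameter logistic (not 5PL) fitted by
  unweighted least squares on the log10-concentration axis — standard
  EIA practice with eight standard levels. Fit refuses extrapolation
  outside the validated 25–3200 pg/ml span.
- Duplicate CV is computed on concentrations (not ODs); the choice is
  documented because the convention is not universal.
- Re-dilution moves one step at a time (1:4 → 1:16 → 1:64); a sample
  still binding < 5% at 1:64 goes to manual re-assay.
- The manufacturer sensitivity (47.9 pg/ml) is metadata: values below
  it are flagged, not floored, because the extended curve's lowest
  standard (25 pg/ml) sits beneath it.
- The mass balance is `conc × dilution × 0.50 ml / (75.0 mg × 3.00/4.00)`;
  pg/mg ≡ ng/g. It is linear in concentration and dilution and invariant
  to simultaneous scaling of solvent and aliquot volumes.

## Hormone profile and pregnancy calling

- Z-scores use the sample (n−1) SD throughout; this reproduces the
  source study's printed within-plate z extremes from its printed
  moments to their printed precision.
- Three baseline definitions are first-class: full-plate mean (the
  published definition), non-pregnant mean (requires labels) and
  full-plate median. All are reported side by side.
- **Calling baseline.** The published threshold ("100% above the
  full-plate average") is self-defeating on plates where a large
  fraction of samples is pregnancy-elevated: the elevation inflates its
  own baseline. The caller therefore estimates its baseline by iterated
  run exclusion — start at the 25th percentile of the profile, detect
  elevation runs, re-estimate the baseline as the mean of samples
  outside the runs (plus a one-sample guard band on each side, since
  each subsample integrates an interval of growth and run neighbours
  are partially elevated), repeat to convergence. Without labels this
  converges to the non-pregnant mean whenever at least roughly a
  quarter of the plate is non-pregnant; with ~63% of a plate elevated
  it still recovers the true baseline to a few percent. Plates elevated
  over ~75% of their length are outside its design range.
- **Rule**: a maximal run of consecutive samples ≥ 100% above baseline,
  with one interior sub-threshold sample tolerated when both neighbours
  qualify (assay-noise tolerance, configurable off). Run duration spans
  the first to last qualifying sample plus half a sample spacing per
  side. Duration > 10 months ⇒ full-term pregnancy (strict inequality:
  exactly 10.0 months is a short elevation); a single-sample run is a
  spike regardless of height.
- **Foetal growth model**: monotone piecewise-linear interpolation
  through the two case-study calibration pairs (39.2 cm ↔ 4 months,
  168 cm ↔ 8 months), extended through (0 cm, 0.5 months) and a
  neonate point (450 cm, 12 months) consistent with published
  mysticete foetal growth rates; all knots configurable. Gestational
  age is rounded to whole months before month-of-year subtraction.
- Calving intervals keep the exact real-year difference and report the
  nearest whole year, matching how such intervals are stated in
  sighting-history studies.

## Mixed model

The stated design — status fixed effect with random intercepts for
whale and for sampling position — is degenerate in its position term:
every position is a singleton within its whale, so the position
intercepts contribute σ²(pos)·I to the marginal covariance exactly as
the residual does. Only the sum σ²(pos)+σ²(resid) is identifiable, and
profiling both numerically destabilises REML (standard errors collapse).
The position component is therefore constrained to zero and reported as
aliased; the fixed-effect estimate and SE are unchanged by the
constraint. With a single whale the model reduces to OLS (explicitly
requested via `allow_single_whale`). Degrees of freedom follow the
within-group convention (observations − whales − fixed parameters); the
significance rule is |t| > 2 and p < 0.05, with no multiplicity
correction (one planned comparison). Across 500 simulated null
replicates the empirical type-I rate is ≈5%; 95% CIs for a 300 ng/g
effect cover it ≈95–99% of the time in the two-whale, 61-sample design.

## Simulator

The generator emulates the case-study conditions: ~3.5 years of growth,
per-year BGR in 16–24 cm/yr, 2-cm subsampling (8–12 samples per year),
an annual δ¹⁵N sinusoid (amplitude 1‰, analytical noise SD 0.15‰, peak
near the end of the fasting season, month 3), a ~130 ng/g lognormal
non-pregnant baseline, multiplicative assay noise with CV 0.10 and
one-sample multiplicative spikes at 0.02/cm (matching the one-to-two
spikes per plate observed in the study's non-pregnant whales).

The latent pregnancy kernel is three linear pieces: a fast onset rise
over the first month to half the peak, a slow climb to the peak at
0.75 × gestation, and a linear decline to baseline ending one month
post-partum. A single linear ramp from baseline to peak was considered
and rejected: it keeps the latent level below the 2× threshold for the
first 1/(m−1) of gestation, so the detected elevation cannot match the
true window and — for any peak multiplier ≤ 5.3 — lasts under 10 months,
contradicting the observed pattern of pregnancies being elevated
essentially throughout gestation ("sustained high" profiles). The peak
multiplier defaults to 6× baseline, inside the observed range of
peak-to-non-pregnant-mean ratios (≈3.7× and ≈9.3× for the two pregnant
study whales). A failed pregnancy follows the same kernel until its
failure month and decays to baseline within a month. Elevation onset is
modelled at conception (a configurable lag is exposed through the kernel
parameters); whether onset truly coincides with conception is unresolved
in baleen data.

What the simulator does **not** emulate: δ¹³C, within-year growth-rate
variation, gumline damage/missing samples, extraction-efficiency drift
near the gumline (the source study saw declining recovery in the newest
baleen), entanglement effects, and pseudopregnancy as a distinct
endocrine state (short elevations stand in for all sub-10-month
phenomena). Recovery results on simulated plates therefore bound what
the pipeline can do under its own assumptions; they do not establish
performance on plates whose noise violates them.

## Problem sizes and determinism

Batch experiments use 200 simulated plates (~32 samples each) for
caller sensitivity/precision and growth-rate recovery, and 100
replicates for mixed-model coverage/type-I behaviour — sizes at which
the Monte Carlo error on the reported rates is a few percent and a full
run completes in seconds. One root seed drives scenario sampling and
per-plate sub-seeds, so batches are reproducible plate by plate; the
analysis pipeline itself is deterministic given a plate and a config
(byte-identical outputs on repeated runs).

## Known limitations

- Conceptions dated from elevation onset inherit the onset-lag
  assumption; the worked examples show a ~0.5–2 month late bias
  relative to true conception at default settings.
- The > 10-month duration rule sits close to the elevated span of a
  12-month gestation; gestations at the short end of the plausible
  10–12-month range would be called short elevations at the default
  threshold unless the multiplier is high.
- The per-position variance component of the published mixed-model
  design is unidentifiable from one plate per whale; our constraint is
  a documented modelling decision, not a fitted result.
- Real plates with damaged gumlines start at > 0 cm; the timeline
  handles gaps, but calls that would begin in missing baleen are
  truncated to the observed span.
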