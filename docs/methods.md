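# Methods

This note documents the model, the synthetic-cohort generator and the
numerical and statistical choices behind `sgascreen`, in the order a reader
would meet them in the pipeline.

## Outcome space and weight charts

A pregnancy's outcome is the pair `(g, z)`: gestational age at delivery in
decimal weeks and the birth-weight Z-score at that age.  Weight is modelled
on the natural-log scale: `log(weight)` is Gaussian with GA-dependent median
and SD, so percentile cut-offs are constant-Z contours (`z < Phi^-1(0.10)`
for SGA<10th, `z < Phi^-1(0.03)` for SGA<3rd, strict inequalities).  GA
comparisons use the half-open convention: "before 37 weeks" means
`g < 37.0` exactly.

The chart shipped as default is a **stand-in**, not a transcription of any
published chart: monotone-cubic (PCHIP) interpolation through median-weight
and log-SD knots with published-style shapes (steep mid-gestation growth
flattening at term; relative spread narrowing from 0.20 at 24 weeks to 0.12
at 43 weeks).  Interpolating a strictly increasing median with a
shape-preserving cubic guarantees the chart invariants (median strictly
increasing, SD strictly positive) everywhere, which the loader also checks.
The chart's overall scale is anchored at configuration-build time so that
the model-implied median birth weight equals the cohort median of 3275 g
(computed on a large fixed-seed probe draw from the calibrated joint);
anchoring rescales all medians multiplicatively and leaves Z-scores, and
hence every SGA label, untouched.  A site can load its own chart from a
`chart:` config block; bit-compatibility with any particular chart software
would require transcribing that chart's coefficients.

## Prior: a two-pathway competing-risks joint density

The prior for `(g, z)` is a mixture of two bivariate Gaussians truncated to
the delivery box `[24, 43] x [-5, 5]`:

* a **term pathway** (weight ~0.96): mean GA near 39.6 weeks, SD 1.30
  weeks, birth-weight Z near standard normal (SD 1.0, correlation 0.15);
* a **placental-dysfunction pathway** (weight ~0.04): broad in GA
  (SD ~5 weeks, mean ~38), centred low in Z (mean ~ -2.1, SD 0.9).

The mixture *is* the competing-risks idea in generative form: most
pregnancies deliver at term with normally grown babies, while a small
dysfunctional fraction delivers over a wide, early-skewed GA range with
small babies.  A single truncated bivariate Gaussian cannot represent such
a population: no parameter choice jointly yields a median GA of 39.5 weeks
with an interquartile range under two weeks *and* ~0.4% of pregnancies
delivering an SGA<10th neonate before 32 weeks of whom ~77% are also below
the 3rd percentile — a weighted least-squares search over the full
single-Gaussian parameter space leaves several of those quantities more
than five binomial standard errors away from their targets.  The
two-pathway mixture reproduces all seven calibrated quantities to machine
precision with clinically sensible values (dysfunction share 4.7%, overall
preterm rate 4.3%, `P(g<32)` 0.46%).

Maternal risk factors act as additive shifts `(dg, dz)` on the means of
*both* pathways, so each woman's prior is a translation of the baseline
density.  Default effects (weeks on `g`, Z units on `z`) follow the sign
and rough size of the risk-factor literature — e.g. smoking `dz = -0.35`,
chronic hypertension `(-0.5, -0.35)`, previous SGA `dz = -0.55`,
nulliparity `(-0.1, -0.12)`, IVF `(-0.25, -0.12)`, diabetes `(-0.3, +0.10)`
— and are deliberately conservative; consequences are discussed under
*Limitations*.

## Generator calibration

`calibrate_generator` solves seven equations in seven unknowns — the
dysfunction share, both pathway mean pairs, the dysfunction GA spread and
correlation, with the remaining shape constants fixed — so that the
*population* reproduces: SGA<10th 14.48%, SGA<3rd 5.99%, SGA<10th <37w
2.01%, SGA<10th <32w 0.40%, SGA<3rd <37w 1.34%, SGA<3rd <32w 0.31%, and
median GA at delivery 39.5 weeks.  Every quantity is an analytic rectangle
probability of the truncated mixture (standard bivariate-normal CDF,
implemented vectorised with Genz's algorithm, accurate to ~1e-14).  Because
maternal effects translate individual priors, the population is a discrete
mixture over shift atoms; the calibration therefore averages the per-atom
truncated rectangle probabilities over the exact atom distribution implied
by the cohort marginals (atoms enumerated from a large fixed-seed probe
draw), so the solved baseline components make the *generated population*
— not just an average woman — hit the targets.  The solver is
Levenberg-Marquardt least squares on transformed parameters; calibration
fails loudly (reporting the closest achievable incidences) if the residual
exceeds 1e-4 in probability, e.g. for internally inconsistent targets such
as a joint incidence above its marginal.

Sampling truncates the *mixture*: a rejected draw re-samples the pathway
together with the point, matching the risk engine's normalised prior on
the box exactly — this identity is what makes self-consistency calibration
(below) exact rather than approximate.

## Biomarkers: MoM conversion and folded-plane likelihoods

Raw biomarker values are converted to MoM by dividing by
`10^expected_log10`, where `expected_log10` is an additive regression on
centred maternal covariates (weight, GA at screening, smoking, race,
conception mode).  The default regressions are documented stand-ins with
literature-style signs (PAPP-A and PlGF rise with screening GA and fall
with weight; smoking lowers PAPP-A and raises PlGF; UtA-PI falls with GA);
the exact covariate list of any published MoM equation would replace them
via `params.json`.  Analyzer-specific terms are representable as
categorical covariates but default to zero.

Given the outcome `(g, z)`, `log10 MoM` of each biomarker is Gaussian with
SD `sigma` and a folded-plane mean

    mu(g, z) = slope_g * min(g - 38, 0) + slope_z * min(z + 1, 0),

zero for pregnancies delivering at or after 38 weeks with Z at or above
-1, and linearly deviating below either knot (UtA-PI up:
`slope_g = -0.015, slope_z = -0.050, sigma = 0.12`; PAPP-A mildly down:
`+0.010, +0.040, 0.25`; PlGF strongly down: `+0.025, +0.060, 0.18`).  The
knots sit below the population bulk so that the median MoM of each
biomarker stays within a few percent of 1 — the expected behaviour of a
correctly specified MoM model — while severe early SGA pregnancies carry
MoM deviations of one to two likelihood SDs.  PAPP-A is configured weaker
than PlGF, matching the consistent finding that PlGF adds discrimination
over UtA-PI whereas PAPP-A adds little.  Biomarkers are conditionally
independent given `(g, z)`.

Mean arterial pressure appears only as an optional `map_mom` cohort column
consumed by the logistic comparator models, generated with a small
dysfunction-linked elevation; it does not enter the competing-risks screen.

## Nested availability and pre-eclampsia co-labels

Biomarker availability is nested by design: PAPP-A in all records, UtA-PI
in 50.8%, PlGF in 27.8% (a subset of the UtA-PI records), independent of
outcomes — so screening with whatever is measured remains calibrated.
Pre-eclampsia is a co-assigned label, not a mechanistic outcome: the four
joint cell targets (preterm/term x SGA/non-SGA, from the overall 1.86% PE
rate, its 32.2% preterm share, and the SGA fractions within preterm and
term PE) are converted to conditional probabilities against the realised
cell sizes, so the expected overall PE rate is exact by construction.  PE
matters to the analysis only through the "SGA without PE" stratification.

## Risk engine

The posterior over `(g, z)` is the prior times the Gaussian likelihood of
each *available* biomarker's log10 MoM, renormalised on a grid (0.05 weeks
by 0.02 Z, trapezoid rule) whose axes additionally contain every plane knot
and every requested percentile/GA cut-off as exact nodes.  Likelihoods are
accumulated in log space and normalised by the maximum before
exponentiation, so extreme MoM values cannot underflow.  Risks are
monotone in both the percentile and the GA cut-off, and halving both grid
steps changes risks by less than 1e-4 (tested).

Cohort screening uses an algebraically identical vectorised path: records
sharing a maternal-shift atom and an availability pattern share one
prior-times-`mu^2` base grid; within each rectangular cell delimited by
the plane knots every plane mean is linear in `(g, z)`, so the
record-specific factor `exp(sum_b x_b mu_b / sigma_b^2)` separates into a
g-vector times a z-vector and the rectangle integrals become blocked
bilinear forms evaluated with matrix products (~0.15 ms per record; 50 000
pregnancies in under 10 s).  The fast path is tested to agree with the
per-record reference engine to a relative 1e-9.

## Validation statistics

* **Detection rate at fixed FPR.** The threshold is the smallest observed
  risk value whose control false-positive fraction does not exceed the
  target (ties broken toward a lower realised FPR; cases count as detected
  at or above the threshold).  Wilson score 95% CIs on the DR.
* **AUC.** Mann-Whitney pair probability with ties counted 1/2; DeLong
  variance for the 95% CI.  Equality with brute-force pair counting is a
  property test up to n = 200.
* **Calibration.** Logistic regression of the outcome on logit predicted
  risk.  The *slope* comes from the joint recalibration fit; the headline
  *intercept* is calibration-in-the-large (slope fixed at 1, logit risk as
  offset), the standard summary of overall over/under-prediction — the
  jointly fitted intercept is also reported.  Perfect calibration gives
  (1, 0).  Risks at the unit-interval boundary are clipped to
  `[1e-9, 1 - 1e-9]` with a logged warning; a constant risk column is
  flagged as a degenerate fit.  A decile observed-vs-expected table
  accompanies each fit for calibration plots.
* **McNemar.** Both models thresholded at their own fixed FPR; among cases,
  the exact binomial test on discordant pairs when their count is below
  25, otherwise the continuity-corrected chi-square.
* **"SGA without PE".** Cases are SGA pregnancies without PE; SGA
  pregnancies *with* PE are excluded from the evaluation subset entirely
  (controls are the non-SGA records).  This is one of two defensible
  conventions; it is applied uniformly.

Self-consistency is the central check: screening a cohort generated from
the same parameters must be calibrated.  At n = 50 000 the fitted slope is
within a few hundredths of 1 and the in-the-large intercept within a few
hundredths of 0 (the joint-fit intercept has a sampling SD of ~0.11 at the
~1000 cases such a cohort contains, which is why the in-the-large form is
the headline intercept).

## Problem sizes

The test and acceptance runs use the study-scale sizes throughout: the
incidence and descriptive checks simulate the full 35 170-pregnancy cohort;
self-consistency calibration screens 50 000 pregnancies; the discrimination
-ordering checks use 100 000 pregnancies with complete biomarker
availability; sampling oracles use 10^6 draws; the whole suite runs in
about a minute on one core.

## Limitations

* All default coefficients — chart knots, MoM regressions, likelihood
  planes, maternal effects — are documented stand-ins with
  literature-style signs and magnitudes, not published parameter sets;
  anyone needing a specific published model must load its coefficients.
* Maternal-factor effects are conservative, so maternal-factors-only
  discrimination (AUC ~0.54 for preterm SGA) is weaker than real cohorts
  report (~0.70); the biomarker combinations span the realistic AUC range.
  Qualitative orderings are unaffected.
* The generator emulates marginals, the outcome joint, and nested
  missingness, but not multi-center heterogeneity (site or analyzer
  effects), covariate-outcome dependences beyond the additive shifts, or
  upstream exclusions (terminations, anomalies) — excluded records exist
  only as the I/O layer's validation-rejection path.
* Biomarker conditional independence given `(g, z)` is an assumption;
  real biomarker panels are cross-correlated, which would reduce the
  incremental value of each added marker.
* Passing self-consistency calibration shows the engine inverts the
  generator's model exactly; it cannot show that this model family fits
  any real population.
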