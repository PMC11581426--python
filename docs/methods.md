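# Methods

This note documents the models and procedures implemented in `smx`, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical decisions that were genuinely open.

## Photobleaching step counting

**Model.** A diffraction-limited spot containing *k* tagged proteins emits
a fluorescence trace that starts at `baseline + Σ heights` and loses one
fluorophore's worth of intensity at each irreversible bleach event; the
number of downward steps estimates the copy number.  Camera noise is
modeled as additive Gaussian (EMCCD readout at moderate gain).

**Filter.** The Chung–Kennedy filter shuttles a backward window
`[t-W, t)` and a forward window `[t, t+W)` along the trace and outputs a
convex combination of the two window means, weighted by inverse window
variance (exponent *p* = 1).  The quieter side dominates, so plateaus are
averaged but the transition is confined to a single frame.  Degenerate
cases are total: a zero-variance window takes the full weight; two
zero-variance windows (e.g. the exact transition frame of a noiseless
step) average equally; windows shorter than 2 frames carry no variance
evidence and get zero weight (edge frames use the other window).  Windows
shrink at the trace ends; nothing is padded.

**Candidate detection.** The approximate differential is the central
first difference of the filtered trace (a forward difference is available).
Candidates are local maxima of |differential| strictly above the peak
threshold; maxima on adjacent frames keep the larger value.

**Validation.** For each candidate, the step height is the difference of
the flanking raw-segment means (segments bounded by neighboring candidates
and the trace ends) and the t-statistic is |height| divided by the pooled
variance of the *filtered* flanks.  One guard frame adjacent to each
candidate is excluded from segment statistics because the filter smears
the step across exactly one transition frame.  Candidates with t ≥ 0.1 are
kept; zero-variance flanks with nonzero height are kept with t = ∞; the
fitted trace is the per-segment mean of the raw data between validated
steps, which is the least-squares piecewise-constant fit for those
breakpoints.

Measuring the regional variance on the filtered rather than the raw trace
is a deliberate design choice: the candidates are found on the filtered
signal, and at a realistic camera scale (~1000 counts per fluorophore,
noise SD ~125) a raw-variance denominator of ~1.6·10⁴ counts² would drive
every genuine step below the 0.1 threshold, while the filtered residual
variance (~σ²/W) puts genuine steps near t ≈ 1 and false candidates near
t ≈ 0.02.  Both the raw-variance and the SD denominators remain available
as configuration (`filtered=None`, `denominator="sd"`).

**Defaults.** Window 12 frames; peak threshold 75 counts; t-threshold 0.1.
All three are instrument-scale dependent configuration, not constants.

## Synthetic bleaching traces

`generate_trace_set` draws per-trace fluorophore counts from a
stoichiometry weight vector (default 0.63/0.24/0.13 over 1/2/>2), bleach
frames uniformly over the movie, and heights lognormally around 1000
counts (CV 0.1) on a 200-count baseline.  Movies default to 500 frames
(25 s at 50 ms exposure).  Two constraints make the planted truth
recoverable *in principle*:

* **Minimum step separation, 24 frames (= 2 × window).**  Two bleach
  events inside one filter response are unresolvable by any step counter;
  moreover, between events closer than two windows both shuttling windows
  straddle a step and the filter cannot settle to the intermediate level,
  producing spurious differential peaks.  The default models resolvable
  events; an analysis of unresolvable coincident bleaching belongs to the
  generator's non-goals.
* **Edge margin, 12 frames**, so the pre-bleach level and the final
  baseline are both observed.

Bleach times are uniform by default because step detection must not
depend on the bleaching kinetics; an exponential law can be emulated by
passing explicit `TraceGroundTruth` objects.  The generator does not model
blinking, triplet states, or partial fluorophore maturation (a
`detection_efficiency` knob on the localization-field generator covers the
sub-unity labeling case for cluster analysis).

## SMLM localization processing

**Ingest.**  Tables carry one row per blink: `x_nm, y_nm, frame,
precision_nm`.  Rows above the 40 nm precision threshold are dropped (the
standard quality cut); pixel-unit tables are converted with the camera
pixel (103 nm default).

**Blink consolidation.**  Localizations are sorted most-precise-first
(ties by x, y, frame, so results are independent of row order) and a
greedy pass claims each unclaimed localization as a seed, absorbing every
unclaimed localization within the seed's precision radius.  The pass
repeats until no merge occurs, making the operation idempotent by
construction; because objects carry inverse-variance weights, the fixpoint
equals a direct weighted mean over the original members, object precision
is the propagated error `1/sqrt(Σ σ_i^{-2})`, and `Σ n_merged` always
equals the input count.  Two interpretations the description leaves open
are exposed as switches: the merge radius uses the seed's precision
(default) or the symmetric maximum of the two precisions
(`radius_rule="symmetric_max"`); seeds are the most precise localizations
(default) or the least precise (`seed_order`).

*Known limitation:* the distance between two blinks of the same
fluorophore is Rayleigh-distributed with mean ≈1.25·σ√2 ≈ 1.77σ, so a
merge radius of exactly one precision leaves most repeat blinks unmerged
and inflates apparent stoichiometry whenever fluorophores blink more than
once.  `radius_factor` scales the radius (2–3 captures the bulk of repeat
blinks at the cost of fusing genuinely distinct molecules closer than
that); the default stays at the literal 1.0.

**Clustering.**  Objects strictly closer than 160 nm are joined; clusters
are the connected components (single linkage), so chains group
transitively and objects at exactly 160 nm stay separate.  Whether the
original rule was transitive is not decidable from its description, so a
complete-linkage variant is shipped for sensitivity analysis
(`linkage="complete"`).  Stoichiometry fractions are reported per
replicate over the 1 / 2 / >2 classes with mean ± SD across replicates.

**FRC resolution.**  Localizations are split into odd/even-frame halves
(a random split is available), each half rendered as a 2-D histogram at
10 nm pixels, and the FRC curve is the ring-wise normalized
cross-spectrum.  The resolution is the inverse of the first frequency
where the (3-ring moving-averaged) curve drops below the fixed 1/7
threshold, linearly interpolated between rings.  Two degenerate outcomes
are reported explicitly rather than as numbers: `no_crossing` (the curve
never drops below threshold — resolution finer than the rendering
Nyquist) and `no_correlation` (the mean FRC of the first four rings is
below 0.5 — the halves share no structure, as for independent noise).

## Class averaging of dimers

Each two-object cluster is rigidly mapped to a common frame: midpoint at
the origin, inter-object axis along x, so the members land at (−d/2, 0)
and (+d/2, 0) with their precisions carried as rendering widths.  Which
member lands left is randomized per dimer (seeded): sorting by any member
property would bias the profile, and randomization enforces the x → −x
symmetry of the average.  Each member contributes a unit-mass isotropic
Gaussian of SD equal to its width; the surface integrates to 2 × n_dimers.

The separation is read off the 1-D profile (surface summed over the
transverse axis): the two highest interior local maxima, each refined by
a 3-point quadratic fit, give the peak positions.  A unimodal profile
returns separation 0 with a flag.  Grid spacing defaults to 1 nm over an
extent covering 1.5× the largest separation plus 5 Gaussian widths; the
estimate changes by <0.05 nm under grid halving.

Note the estimator reports the *mode separation of the rendered mixture*,
not the planted distance: for two equal Gaussians at ±d/2 with width σ the
modes sit slightly inside ±d/2 once σ/d is appreciable (≈0.2 nm inward at
d = 12.7 nm, σ = 4 nm; the profile merges to a single mode when d ≤ 2σ).
This is the same quantity a surface-plot reading of the class average
yields.

## Two-color coincidence and turnover

Spots are matched across channels when strictly closer than the channel
offset (2 px default, Euclidean distance on integer pixel coordinates).
Matching is greedy nearest-first and one-to-one — candidate pairs sorted
by distance, accepted while both spots are free — because "any spot within
the offset" counting double-counts at high density; that literal counting
survives as `mode="any_within"` for compatibility.  Populations follow by
arithmetic: A-only = n_A − n_c, B-only = n_B − n_c, mixed = n_c, fractions
over n_A + n_B − n_c distinct complexes.

**Chance correction.**  `chance_coincidence` redraws channel-B positions
uniformly and re-matches.  By default only the *unmatched* spots of both
channels are used: with planted pairs present, randomizing all of B
estimates the chance rate of a field with B-density n_B/A rather than the
density of unpaired molecules (n_B − n_c)/A, overstating the background by
roughly the ratio of the two densities.  The corrected planted-fraction
estimator is (observed − chance)/n_A.  Full randomization remains
available (`exclude_matched=False`) and matches the Poisson approximation
n_A·(1 − exp(−ρ_B πr²)) on unstructured fields.

**Synthetic two-channel fields.**  A fraction of channel-A spots receives
a B partner displaced by Gaussian jitter (default SD 0.3 px, a realistic
channel-registration residual).  Since spots are integer pixels, planted
distances include rounding; at 0.3 px jitter fewer than 0.3% of planted
pairs land at ≥2 px, so the planted fraction stays recoverable.  Larger
jitter moves planted pairs outside the offset and the recovered fraction
drops accordingly — a property of the offset rule, not of the generator.

## Regional turnover statistics

Input is a tidy per-mouse, per-region table of (a-only, b-only, mixed)
fractions.  Regions are summarized as mean ± SD over mice; one-way
fixed-effects ANOVA (scipy) tests for regional differences per fraction
type, with the degenerate all-equal case returning (F = 0, p = 1);
pairwise two-sample t-tests locate the source of significance
(pooled-variance Student by default — the classical post hoc test — with
Welch as an option; raw p-values by default, Bonferroni alongside,
matching the convention of reporting uncorrected pairwise values).
Fractions are analyzed on the raw proportion scale as plotted;
arcsine/logit transforms were considered and left out of the default path
because the analysis is descriptive, not inferential modeling of
proportions near the boundary.  Pearson's R with the two-sided t-transform
p-value (n − 2 df) correlates regional mixed fractions against
user-supplied protein half-lives; half-life values are external
measurements and are never bundled as facts — examples and the acceptance
script generate clearly-labelled synthetic half-life tables with a planted
linear relation.

The cohort generator plants region-dependent mixed fractions (defaults:
isocortex 0.19, olfactory bulb 0.04 — measured-scale anchors — and
hippocampus 0.12, cerebellum 0.08, subcortex 0.10 as plausible synthetic
intermediates), a region-independent a-only fraction, and b-only as the
remainder, for 6 mice per region with SD 0.03.

## Spot detection

`find_spots` implements topographic prominence with ImageJ *Find Maxima*
semantics: pixels are processed in descending intensity (ties broken by
row-major scan order, first wins) through a union-find; when two
components meet, the meeting pixel is the saddle and the lower peak's
prominence is fixed as peak − saddle; surviving peaks score peak − image
minimum (so a constant image yields nothing).  Spots with prominence
strictly above the parameter are returned, intensity-sorted, with 8-way
connectivity.  Traces are measured as the mean (or sum) over a square
aperture (3×3 default; the choice is configuration because the measured
aperture is not dictated by the detection step); apertures crossing the
image edge are measured over in-bounds pixels and flagged.  No sub-pixel
refinement is applied — the 2 px coincidence rule operates on integer
pixel centers.

## Problem sizes and tolerances in the test suite

The end-to-end checks run at sizes chosen to make binomial tolerances
meaningful on one CPU: 1000 traces for exact noiseless recovery and for
the SNR-8 recovery floor (≥95%); 10⁵ traces for stoichiometry-distribution
recovery within 3 binomial SDs per bin; 500 random fields (≤200 objects)
for clustering-oracle equivalence; 1000 planted dimers for the ±0.5 nm
separation-recovery band; 10⁴ channel-A spots for coincident-fraction
calibration within 3 binomial SDs; 10⁴ null replicates for test-size
calibration at α = 0.05.  Statistical agreement with reference
implementations is asserted at 10⁻⁸ (statsmodels ANOVA/t-tests) and 10⁻¹²
(hand-computed Pearson R).

## Limitations

* Localization ingestion assumes upstream PSF fitting and drift
  correction; no 3-D support.
* The blink model (geometric count, isotropic Gaussian displacement of
  exactly one precision SD) ignores dark-state kinetics and frame-to-frame
  correlation; consolidation quality on real data depends on the true
  blink statistics (see the radius-factor note above).
* The bleaching generator's Gaussian noise omits the photon-number
  dependence of shot noise within a trace; `render_stack` provides Poisson
  noise at the image level for end-to-end tests.
* Class averaging handles stoichiometry-2 clusters only; no rotational
  search or multi-reference alignment.
* Coincidence analysis assumes pre-registered channels; offsets beyond the
  matching tolerance must be corrected upstream.
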