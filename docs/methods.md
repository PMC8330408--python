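# Methods

This note documents the measurement conventions, the statistical models,
the synthetic-data generator and its calibration, the numerical choices,
and what the package's passing tests do and do not establish.

## Measurement model

**Timing.** Frames are 0-based; an interval is the closed-open frame range
`[start, end)` and its duration is `ceil((end − start)·1000/fps)` ms
(default fps 30). The ceiling convention was chosen because the observable
millisecond grid of a 30 fps recording under it is
{0, 34, 67, 100, 134, 167, 200, …}, which is the grid that frame-accurate
VFSS timing measures are reported on; `round` and `floor` conventions are
available via configuration. Swallow reaction time is signed: a hyoid
burst preceding bolus arrival at the mandibular ramus yields a negative
value, which is preserved because clamping at zero would bias cohort
means. All other intervals are also computed signed rather than raising,
because independently jittered pre-consensus ratings can invert a short
interval (the hyoid-burst-to-UES-opening interval has a median of ~3
frames); negative non-reaction-time durations are logged.

**Anatomical scaling.** The anatomical frame has its origin at the
anterior-inferior corner of C4, Y unit vector toward the anterior-inferior
corner of C2 (superior positive), X the perpendicular with anterior
positive, both divided by the pixel spine length L = |C2AI − C4AI| and
multiplied by 100 (units %(C2–4); areas use L² and %(C2–4)²). Input pixel
coordinates follow the image convention (y down). Because the imaging
orientation is not standardized, a `facing` flag ("left"/"right" lateral
projection) selects which perpendicular is anterior; the default is
"left". Every scaled output of the parameter record (norms, lengths,
areas, durations) is invariant under any similarity transform of all pixel
inputs — including a y-flip — which the test suite verifies.

**Hyoid kinematics.** The radial position is the Euclidean norm of the
anatomically transformed hyoid position. Peak XY position is the maximum
over `[hyoid_burst_onset, swallow_rest]`. The **hyoid burst duration** is
defined here as the interval from hyoid burst onset to the (first) frame
of peak radial position. This is a documented package default: the
quantity is used in the correlation/family structure without a published
operational definition, and this choice makes the burst window coincide
with the numerator window of hyoid speed, defined as (peak − minimum
radial position between burst onset and the peak frame) divided by the
burst duration. The minimum is taken inside the burst (not over the whole
track) because the ±10 lead-in/lead-out frames are context, not movement.
A zero-length burst leaves the speed missing (logged), never infinite.

**Polygon areas** use the shoelace formula (absolute value, halved);
empty or <3-vertex input gives area 0. A Monte-Carlo rasterization oracle
in the tests confirms the implementation to <1% on random simple polygons.

**Multiple swallows.** When a bolus elicits more than one swallow, the
annotation's event set describes the initial swallow (matching the
"initial swallow" PAS convention) and the rest frame marking the end of
the final swallow; residue is measured at that final rest frame. `pas_max`
is the worst PAS score across the bolus's swallows. Missing events
propagate as missing parameters with a logged participant/bolus context;
nothing is imputed.

## Agreement and consensus

Pre-consensus agreement per item: percent absolute agreement within the
item's threshold, mean absolute difference, and ICC(2,1) — two-way random
effects, absolute agreement, single measures — computed from the two-way
ANOVA mean squares. The two-way random form is appropriate because raters
are randomly assigned from a pool. Default flag thresholds (±3 frames for
events, ±4 %(C2–4) for UES diameter, ±10 %(C2–4)² for pharyngeal areas,
±1 %(C2–4)² for residue, exact match for PAS/LVC/swallow count) are
inferred from the agreement levels the protocol reports; the protocol's
own threshold table is not public, so all thresholds are configuration.

Consensus merging: flagged items require explicit resolutions (an integer
frame, a categorical label, or "a"/"b" selecting a rater's contour —
an arbitrary scalar cannot be embedded back into pixel vertices);
unflagged event frames merge to the round-half-to-even mean, unflagged
categorical items take rater A, and pixel data (landmarks, track,
contours) merge by coordinate averaging. Event-order invariants that
independent rounding can break are re-clamped and logged. The pipeline's
automatic resolution policy (rounded-mean frames, rater-A categorical and
geometry) stands in for the human consensus meetings of the real
workflow, which cannot be automated.

## Statistical stage

Models run on participant means (the bolus is not an independent unit),
except the multiple-swallow logistic model, which runs on bolus-level
rows because sip volume varies per bolus and the per-ml effect is only
estimable there. Hierarchical OLS per outcome: stage 1 age, stage 2
+ male indicator (coefficient = male − female difference), stage 3 + sip
volume, skipped for pharyngeal area at rest (a measure taken at rest,
independent of swallowing). Raw R² is reported per stage (monotone
non-decreasing; ΔR² ≥ 0); adjusted R² is carried alongside. Each stage's
added predictor is Wald-tested against the outcome's Bonferroni family
alpha, `round(0.05/m, 3)` for a declared family of m related parameters.
Family membership is declarative configuration rather than derived from
the correlation screen: the connected components of the |r| > 0.25 graph
would merge the two timing families (LVC duration correlates with members
of both), so the screen is advisory. Defaults: {HYB→UESO interval, hyoid
burst duration, time-to-LVC} at α = 0.017; {UESO duration, LVC duration,
UES diameter, peak XY, hyoid speed} at α = 0.01; {pharyngeal areas and
residue} at α = 0.01; everything else at 0.05.

Quantiles use linear interpolation between order statistics (the common
numeric default; configurable in principle via the descriptives layer).
2×2 odds ratios use OR = ad/bc with a Woolf log-normal 95% CI and the
Haldane–Anscombe 0.5 correction when a cell is zero (recorded in the
result); sips are dichotomized strictly above vs at-or-below 16 ml.
PAS and LVC-integrity logistic models exist but the pipeline skips them
when the minority class covers fewer than 5 participants, mirroring the
sparsity of unsafe swallows in healthy cohorts.

## Synthetic-data generator

The generator emulates the study conditions: n = 76 (38 male, 38 female),
ages uniform on 21–82, 3 thin-liquid boluses per participant, 30 fps,
pixel spine length ~ N(100, 8²) px.

**Effect structure.** Each continuous parameter follows

    value = intercept + b_age·(age − 70) + b_sex·male
            + b_sip·(sip − 14) + u_participant + e_bolus

with intercepts anchored at age 70 to the older-cohort medians (sip
volume 13.58 ml, swallow reaction time 200 ms, HYB→UESO 100 ms, UESO
duration 500 ms, time-to-LVC 134 ms, LVC duration 534 ms, peak XY 176,
speed 117, UES diameter 23, pharyngeal area 2/63, residue ≈0) and the
published effect sizes as slopes: age 4 ms/yr (reaction time), 1.4 ms/yr
(UESO duration), 2.4 ms/yr (LVC duration), 0.11 %(C2–4)/yr (UES
diameter), 0.31 %(C2–4)²/yr (area at rest), 0.035 %(C2–4)²/yr (area at
maximum constriction — the printed 3.5 value is inconsistent with the
cohort median of 2, so the 100-fold smaller reading is used and
documented); sex +4.69 ml (sip volume) and +11 %(C2–4)² (area at rest);
sip −2.4 ms/ml (HYB→UESO) and +0.27 %(C2–4)/ml (UES diameter). Sip volume
itself is base 11.24 ml + 4.69·male + participant noise (SD 4) + bolus
noise (SD 3), centred at 14 ml in the effect equations so intercepts stay
interpretable near the observed median.

**Noise calibration.** Where a variance-explained fraction is published
(6% reaction time, 12% UESO duration, 8% LVC duration, 10% UES diameter
and pharyngeal areas for age; 13% for sip on HYB→UESO), the residual SD
at the participant-mean level is the closed form
σ = |slope|·sd(x)·√((1−R²)/R²) with sd(age) = 61/√12 ≈ 17.6 and
sd(mean sip) ≈ 4.36; it is split into equal participant- and bolus-level
components with σ_p² + σ_b²/3 = σ². Parameters without a published R²
take their SD from the printed interquartile range (IQR/1.349).
Residual noise is drawn multivariate-normal with a correlation matrix
reproducing the published pairwise correlation structure (e.g.
time-to-LVC vs HYB→UESO 0.496, time-to-LVC vs LVC duration −0.599, peak
XY vs UES diameter 0.549), plus 0.35 among residue sites; the default
matrix is positive definite (minimum eigenvalue ≈ 0.10) and a non-PSD
user matrix is rejected with a pointer to nearest-correlation projection.

**Floors and truncation.** Non-negative quantities are truncated at zero
(not resampled) and the truncation rate is logged. For every parameter
carrying a calibrated effect the rate is well under 5%, so censoring
cannot meaningfully bias the recovered slopes — with one deliberate
exception: pharyngeal area at maximum constriction (median 2, calibrated
SD ≈ 2.3) and the residue components have genuine mass at the zero floor;
for them truncation *is* the intended zero-inflation. The OLS age slope
of the floor-censored constriction area is consequently attenuated
(~0.024 recovered vs 0.035 generated), which the recovery tests assert
directionally rather than exactly.

**Timing consistency.** Millisecond values are snapped to the fps grid
before synthesis (k = round(ms·fps/1000), ms = ceil(k·1000/fps)); the
hyoid burst duration is kept ≥ 1 frame; the minimum radial hyoid position
is derived as peak − speed·duration (clamped ≥ 1 with the stored speed
re-derived), so peak, minimum, speed and burst duration are exactly
mutually consistent and `summarize_bolus(synthesize_annotations(v)) = v`
holds with timing exact and geometry to 10⁻⁶ relative (measured: ~10⁻¹²).

**Annotation synthesis** lays out event frames from the snapped
intervals (bolus-past-mandible at frame 120, leaving room for negative
reaction times), a half-cosine radial hyoid trajectory rising from the
minimum to the peak over the burst and partially relaxing afterwards,
axis-aligned rectangles of the prescribed scaled area, and a segment of
the prescribed scaled length — all mapped into a randomly rotated and
translated pixel frame with the participant's spine length. **Rater
simulation** adds discretized-normal frame jitter (SD 1 frame; order
invariants re-clamped), normal pixel jitter (SD 1 px) on every annotated
coordinate including the spine landmarks, PAS ±1 flips with p = 0.03 per
rater (two independent raters then agree exactly on ≈94% of PAS ratings)
and LVC-integrity flips with p = 0.015 (≈97% agreement). All randomness
derives from one seed via `SeedSequence` spawning.

**Multiple swallows** follow a bolus-level logistic model with log-odds
slope 0.09 per ml of sip volume. The published phrasing ("increasing the
odds … by a factor of 0.09") is internally odd — a factor below 1 would
decrease odds — and is read here as a log-odds slope (OR ≈ 1.094/ml);
the intercept −1.386 puts ~20% of boluses at the centring sip volume in
the multiple-swallow class.

## What the simulations do and do not show

The generator produces normal (floor-truncated) residuals, exact sex
balance, uniformly distributed ages, a constant bolus count, rectangle
contours and a smooth hyoid path. Real data have skewed residue
distributions, convenience-sampled age gaps, occasional missing boluses,
irregular contours and raters whose errors correlate with image quality.
Passing recovery tests therefore show that the pipeline is *internally
consistent* — it measures what the annotations encode and recovers the
effects it was told to plant, through rater noise and consensus — not
that the published cohort estimates would replicate on new participants.

## Problem sizes and numerical choices

The recovery harness uses 200 cohorts (seeds 1–200) on the generator's
true parameter tables (~10 s) — the quantity of interest is the
regression stage's recovery of the planted effect structure — and the
full annotation → raters → consensus → measurement route is exercised
over 30 cohorts in the test suite (~25 s), where every non-censored
effect is likewise recovered within 2 Monte-Carlo SEs. Null type-I-error
calibration uses 500 zero-effect cohorts. Mean recovered values at seeds
1–200: 4.00 ms/yr, 4.63 ml, 1.38 ms/yr, 2.43 ms/yr, 0.111 %(C2–4)/yr,
−2.39 ms/ml, and a mean age-only R² of 12.4% for UESO duration — all
computed at run time by `scripts/acceptance.py`.

Degenerate inputs: coincident spine landmarks raise a geometry error;
empty vectors raise undefined-statistic errors; rank-deficient designs
raise naming the collinear predictors; complete separation raises with a
suggestion to use a penalized fit (never applied silently); zero rater
variance yields a warned missing ICC. Ties in the hyoid peak resolve to
the first peak frame; consensus frame rounding is half-to-even.

## Known limitations

* No video or DICOM processing, no automatic landmark/hyoid detection,
  no swallow segmentation: annotations are trusted inputs.
* Exactly two raters; no Krippendorff/kappa statistics.
* No mixed-effects modelling: participant means discard within-subject
  correlation structure beyond the averaging itself.
* The hyoid-burst-duration definition and the agreement thresholds are
  documented package defaults, not published constants.
* The floor-censored constriction-area slope is attenuated by design;
  treat its recovered magnitude as a lower bound.
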