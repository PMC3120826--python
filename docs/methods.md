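# Methods

## The display and its generative model

A stimulus movie is a stack of luminance frames in [0, 1] with three
static regions: an irregular central disc, a surrounding annulus, and a
neutral-gray background at the mean luminance (0.5). Dots are single
pixels drawn i.i.d. Bernoulli(d) with d = 0.5 by default; a region's two
luminance levels are `mu * (1 - c)` and `mu * (1 + c)` for Michelson
contrast c, symmetric about the mean so that contrast manipulations never
change the expected luminance. Defaults mirror the study conditions:
256×256 frames at 25 px/deg, a 6.2-deg-diameter center, 6 deg/s
translation, 75 Hz, 4 s (300 frames), contrast 1.0.

**Center.** A hidden texture translates rigidly behind the static
outline at an integer number of pixels per frame (2 px/frame at the
defaults). Sampling the moving texture through the fixed mask produces
exactly the accretion-deletion structure of interest: content crossing
the leading boundary disappears, fresh texture enters at the trailing
boundary. Any spec whose per-frame displacement (or its row/column
components) is not an integer is rejected rather than rounded: sub-pixel
resampling would blur the binary dots and change the per-pixel transition
statistics that the Ideal Observer's likelihoods are derived from.

**Outline.** The irregular outline is a radial-frequency pattern,
`r(theta) = R (1 + A * sum_{k=3..7} sin(k theta + phi_k))` with A = 0.1
and phases drawn from `center_outline_seed`. The radius stays positive,
so the region is star-shaped (hence simply connected), and the enclosed
area is nearly independent of the phases (spread < 1% over 100 seeds).

**Surround.** Each surround dot survives to the next frame with
probability equal to the temporal coherence (identity mapping: 100% =
static dots, 50% = random flicker); non-survivors are resampled at
density d, so density is stationary. The chance that an independently
resampled pixel lands in its previous state is m = d² + (1−d)², which is
why raw consecutive-frame agreement a overestimates survival; the probe
`measure_survival` inverts a = s + (1−s)·m.

**Seeding.** The center texture, the surround process and the near-model
switch process draw from three independent child streams of a single
`rng_seed` (numpy `SeedSequence.spawn`). Consequently two specs that
differ only in surround parameters have *bit-identical* center pixel
streams — the property that makes "the AD information was identical
across conditions" assertable rather than approximate.

## Ideal Observer

The observer decides between the two depth-order interpretations using
only the deletion band ("area 3"): center pixels p such that p + d·u
falls outside the outline, where d is the per-frame displacement and u
the unit motion vector. Its width equals the displacement, and it hugs
the leading edge of motion. Per frame pair and area-3 pixel it adds
`log P(x' | x, F) − log P(x' | x, N)` where x, x' are the pixel's
binarized states in consecutive frames.

The two transition models are derived from the generator, not from any
published closed form:

- **F (center far).** The pixel's dot is deleted and replaced by texture
  streaming in from an independent site; given only the pixel's own prior
  state, the next state is a fresh Bernoulli(d) draw, correlated with the
  prior state only by chance (match probability d² + (1−d)² = 0.5 at
  d = 0.5).
- **N (center near).** An un-occluded near surface keeps its dots: the
  state persists, switching (on↔off) with probability r.

A per-pixel-marginal formulation is used deliberately. A fully
frame-conditioned likelihood would have to evaluate the area-3 content's
*destination* pixels, which lie beyond the outline in the surround; the
observer here is the strongest rule that uses center pixels only, which
is what makes its surround-independence exact (the cumulative LLR is a
function of center pixels alone, bit-identical under any surround
manipulation). The near model's stationary outline is a genuine
ambiguity of the display; the package resolves it by evaluating the same
retinal area-3 pixels under a persistence model, and anchors both models
to a brute-force frequency oracle: transition frequencies tallied from
generated movies match the model tables to within ±0.01 at 10⁶ draws
(tests), with observed agreement better than ±0.001.

Numerical choices: probabilities inside logs are floored at eps = 1e-12;
a cumulative LLR of exactly zero (e.g. zero displacement, hence an empty
evidence region) returns an explicit "no-evidence" outcome, never a coin
flip. The default switch rate r = 0.05 treats the near surface's dots as
mostly persistent but noisy; r is a free parameter of the observer (the
models are indistinguishable at r = 2d(1−d), and r → 0 degenerates the
likelihood), and the same value drives the explicit near-model generator
(`generate_sequence(..., depth_model="N")`), which overrides area-3
pixels to persist with switch probability r so that the observer's N
model can be validated against sequences actually generated under it.
The observer receives the true mask, displacement, direction, density
and r (ideal-observer convention: nuisance parameters known).

## Optic flow and the accretion-deletion zone

`horn_schunck` minimizes the classic brightness-constancy plus
α²-weighted smoothness energy with Jacobi averaging updates and the
original 2×2×2 cube derivative estimators. Two implementation choices:

- Cube derivatives live on the inter-pixel grid; they are symmetrically
  interpolated back to pixel centers so that the returned fields match
  the frame shape, and every spatial summation is grouped so mirrored
  inputs yield bit-exact mirrored (sign-flipped) flow — a strong
  regression guard on the discretization.
- Binary dot images are not differentiable, so frames are Gaussian
  pre-smoothed (σ = 2.0 px default) before derivative estimation.

Defaults α = 0.2 and 400 iterations were fixed by measurement on a known
rigid translation of a 50%-density dot texture: at this contrast the
recovered interior flow is within 0.03 px/frame of the true 2 px/frame,
while α = 1.0 with 200 iterations recovers only ~0.3 px/frame (the data
term is too weak relative to α² for the Jacobi iteration to converge in
any practical budget). The iteration energy is recorded and is
non-increasing in all tested configurations.

`detect_ad_zone` implements "no flow-consistent correspondence": the
next frame is warped back by the dominant velocity of the flow field
(median over pixels faster than half the maximum speed, snapped to the
integer pixel grid, matching the generator's on-grid motion) and the
absolute difference is averaged over up to 30 frame pairs. Rigidly
translating dots match their correspondence exactly; deleted dots match
only by chance (rate 1−m = 0.5), so their time-averaged difference
concentrates near half the on−off step. The default threshold is half
the dot luminance *amplitude* (a quarter of the step), the midpoint
between the two populations. Cleaning removes connected components
smaller than 8 px — the genuine deletion band is a long thin arc that a
conventional 1-px morphological opening destroys in the static-surround
condition (measured: opening drops the Jaccard overlap with the true
band from ~0.94 to ~0.46). Aggregation over pairs is required because a
single pair can only ever flag ~50% of the band.

Self-calibrated bounds (frozen from 50 default-scale seeds): Jaccard of
the detected center zone against the true deletion band, and between the
static- and flicker-surround conditions, has a 5th percentile of 0.88
(J_MIN in the tests); the mean endpoint error between conditions inside
the center is < 0.07 px/frame against a configured bound of 0.5, and is
always smaller than the surround's (~0.6 px/frame).

## Simulated psychophysics

The human subjects are replaced by a simulated population: subject s
reports "center far" with probability
`lapse/2 + (1 − lapse) * logistic(b0 + b1·c + a_s [+ g])`, with c the
temporal coherence in percent, a_s ~ Normal(0, 0.5) a per-subject
intercept, and g = 15 a gating boost applied when an extraneous
segmentation cue (a center/surround contrast difference) is present.
Defaults b0 = −20, b1 = 0.25 per percentage point put the point of
subjective equality at 80% coherence with a steep but not step-like
slope; lapse = 0.02. Eleven subjects, six coherence levels
{50..100 in steps of 10}, 20 trials per condition per subject, all
trials in seeded randomly interleaved order. These levels and counts are
package defaults for a realistic session, not published values.

Analyses: the logistic fit uses binomial IRLS (statsmodels GLM) on
per-condition counts; "r²" for a logistic fit is reported as the squared
Pearson correlation between per-condition observed proportions and
fitted probabilities, and the definition string travels with every fit
report. Degenerate data (one coherence level, or all responses
identical) raise a `SeparationError` instead of returning a silent fit.
The binomial proportions test is the exact two-sided (minimum-likelihood)
test; by full enumeration at n = 20 its size at α = 0.05 is 0.041. The
residual-normality check bins standardized residuals into
equal-probability normal bins (expected counts ≥ 5, at least 4 bins) and
refers Pearson's X² to chi-square with bins − 3 degrees of freedom; its
null rejection rate, measured over 1000 replicates of 10⁴ Gaussian
residuals, is ~6% (slightly above nominal, as expected when the
location/scale are estimated from the unbinned data).

The six-condition contrast-gating experiment drives the stimulus
generator (low-contrast arm: Michelson 0.25, mean luminance unchanged,
flicker untouched), runs the Ideal Observer on every stimulus — F in all
six conditions, since its evidence excludes the surround — and tabulates
simulated report proportions, which reproduce the qualitative pattern:
flicker without a segmentation cue reverses the percept; a contrast
difference in either direction restores it.

## What the simulation does and does not show

The generator reproduces the display's *statistics* (density, contrast,
coherence/survival, integer-pixel motion) exactly, and all quantitative
claims in the tests are claims about this generative model. It does not
model display gamma, dot anti-aliasing, eye movements, or human internal
noise; simulated observers follow the assumed psychometric form by
construction, so psychophysics tests validate the statistical machinery
and the qualitative gating logic, not human behavior. Published
human-data statistics (e.g. a logistic r² of 0.83) depend on unpublished
subject data and are deliberately not targets. The Horn–Schunck
parameters of the original analysis are unreported; flow results are
therefore asserted as relative properties (center stability vs surround
difference) with the self-calibrated bounds above.

## Scale of the shipped checks

Unit tests run mostly on 96×96, 60-frame movies; the end-to-end checks
use the full 256×256/300-frame scale with 200 movies for the decision
consistency rate, 10⁶ draws for the transition oracle, 200 replicates
for Wald coverage, and 1000 replicates for the chi-square calibration.
The whole suite completes in under two minutes on one CPU.
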