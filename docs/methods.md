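# Methods

This note documents the generative models, the fitting procedures, the
choices made where the design was genuinely open, and what the simulated
results do and do not show.

## Stimulus space and circular arithmetic

All stimuli live on the hue circle of CIELUV LCh coordinates with
lightness and chroma fixed at 70; hue angle in degrees, counterclockwise,
is the only stimulus coordinate. Angles are wrapped to [0, 360), signed
differences use the shortest arc with the antipodal tie broken to +180,
and circular means are the angle of the weighted resultant vector. A
normalized resultant length below 1e-8 is reported as "undefined mean"
(antipodal cancellation): only essentially exact cancellation is
meaningless, and measured response data never hit this threshold. The von
Mises CDF is evaluated through `scipy.stats.vonmises` (accurate to well
below 1e-9, verified against adaptive quadrature in the tests), so the
boundary-model likelihood is smooth for gradient-based optimization.
Degrees are used throughout; radians appear only inside density/CDF
evaluation.

## Trial-schedule generators

The schedule generators reproduce the two designs' arithmetic exactly:

* Experiment 1 — targets at 340° (pink group) or 130° (green group);
  conditions baseline / 180° / 60° toward yellow / 60° toward blue;
  8 blocks (4 conditions × 2, order shuffled), 11 comparison levels × 10
  repetitions per block = 880 trials; element-hue range 30°; per-trial
  common jitter uniform on ±7.5°; comparison steps 4° (baseline), 5°
  (180°), 6° (both 60° conditions).
* Experiment 2 — targets 22.5° below (green group) or above (blue group)
  the observer's green-blue boundary; conditions baseline / across /
  within with distractors ±45°; 9 blocks (3 × 3), 11 levels × 8 reps = 792
  analyzed trials, each block preceded by 11 dummy trials flagged
  non-analyzed; range 25°, jitter ±5°, steps 4°/7°/7°.
* Practice — per condition one 18-trial block using only the three
  outermost levels per side × 3 reps; baseline first, then the 180° block,
  then the remaining conditions in random order (72 trials). The
  Experiment 2 practice includes a 180° block on top of its three main
  conditions; its step size is not separately specified and is set to the
  7° distractor-condition step.

Open choices, resolved as follows:

* **Comparison anchoring.** Comparison offsets are applied relative to the
  *jittered* target mean of the trial. Anchoring to the nominal mean would
  inject the full jitter range as irreducible noise into the psychometric
  levels, inconsistent with small baseline thresholds. The absolute
  comparison mean is logged per trial, so the alternative remains
  recoverable from the CSVs.
* **Jitter** is drawn from a continuous uniform distribution (no
  discreteness is specified anywhere).
* **Interval order** (test or comparison first) is a fair coin per trial
  and is recorded as metadata; the analysis codes responses relative to
  the comparison, so results are invariant to it (tested).
* **Dummy trials** reuse the block's comparison levels; they are excluded
  from every analysis either way.
* Spatial dot positions (6×6 grid, 1° spacing, grid and per-dot location
  jitter) are generated as metadata only and never rendered; no analysis
  uses position.

## The model observer (synthetic-data generator)

The 2IFC observer is the generative counterpart of the analysis chain:

1. Per interval, a weighted circular mean of the element hues. Target and
   comparison elements have weight 1; distractor elements have weight
   `distractor_weight` = *w* per element. *w* = 0 is perfect segmentation,
   *w* = 1 full integration; intermediate *w* is the "mixing" observer
   that fails to fully exclude distractor signals. (Whether down-weighting
   arises from attentional weighting or probabilistic mis-segmentation is
   not distinguishable from the response data; the weighting form is
   implemented.)
2. Independent wrapped-normal noise of SD `internal_noise_sd` (default
   conditions use 4°, a value producing baseline thresholds of a few
   degrees, the order of magnitude seen in trained observers) on each
   interval's estimate. Wrapped-normal (rather than von Mises) noise is
   chosen because it maps directly onto the cumulative-Gaussian analysis:
   the decision variable's SD is √2·noise plus element-sampling variance.
3. Optional central-tendency shrinkage of the *test* estimate toward the
   across-trials grand mean (which equals the nominal target mean in both
   designs), with weight `ctb_weight` (default 0 — the central-tendency
   account predicts effects this package can explore but the default
   observer is purely sensory).
4. Optional subsampling: only `subsample_size` elements, drawn uniformly
   without replacement from the interval's pooled elements, enter the
   average (default disabled).
5. Response = 1 iff the comparison estimate lies counterclockwise (higher
   hue angle) of the test estimate; lapses respond at random with
   probability `lapse_rate` (default 0).

If a weighted mean is undefined (antipodal cancellation), the estimate
falls on the midpoint of one of the two arcs between the opposing
clusters, chosen by a fair coin — the generative mirror of "there is no
meaningful average of opposing hues".

The categorization observer draws m ~ VM(stimulus, κ) and responds with
the category whose boundary arc contains m. The staircase responder is its
two-choice green/blue restriction: green iff the measurement falls on the
lower-hue-angle side of the boundary.

**What the generator does not emulate:** reaction times, memory decay over
the inter-stimulus interval, robust averaging or outlier down-weighting,
crowding or spatial-configuration effects, color-space inhomogeneities,
and strategic (cognitive) compensation for perceived bias. Passing
recovery tests therefore shows that the analysis chain is consistent with
this sensory mixing model — not that human data arise from it; in
particular the asymmetries and large individual differences seen
empirically are outside this generator.

## Psychometric fitting

Two-parameter Bernoulli MLE of Φ((x − μ)/σ), L-BFGS-B with a fixed
deterministic multi-start (one data-driven start from the 50% crossing
plus fixed grid starts), bounds μ ∈ [−90, 90]°, σ ∈ [0.1, 500]° — far
beyond plausible data, for numerical stability only. No lapse parameter by
default (two-parameter fits match the analysis convention); predicted
probabilities are clipped at 1e-10 so degenerate data (all-0/all-1) run to
the bounds without exceptions and are caught by the validity flag. A fit
is valid iff the curve spans [0.25, 0.75] within the tested comparison
range. Responses are pooled over block repetitions by default, with a
per-repetition option.

Bias sign convention: positive bias always points toward the distractor.
A distractor at lower hue angle pulls the perceived test mean down and
hence the PSE to negative offsets, so the reported bias is the PSE times
the sign of the target-to-distractor arc. The "ground truth" against which
bias is measured is the zero comparison offset (the jittered target mean).
The full-integration prediction is half the target-distractor separation
(equal element counts); the 180° condition has no defined prediction and
baseline bias is reported raw with an undefined fraction.

Note one arithmetical consequence of circular averaging: the mixing
observer's expected bias is atan2(w·sin Δ, 1 + w·cos Δ) for separation Δ,
slightly *below* the linear value wΔ/(1+w). At w = 1/3, Δ = 60° this is
13.9°, i.e. ≈46% of the 30° full-integration prediction — the value the
end-to-end recovery tests check against the vector-sum oracle.

## Category-boundary estimation

Cleaning follows the two stated rules on the 5° stimulus grid with
circular wraparound: drop categories with fewer than 4 responses; then,
per category, find runs of adjacent responded stimulus values (a run
breaks at three consecutive empty steps), keep the largest run (by hue
span, ties by response count) as the main group, and remove responses 20°
or more in hue from the nearest main-group member. The procedure is
idempotent and returns an exclusion report.

The boundary model shares one κ across categories (a per-category κ would
not be identifiable from 4 reps per stimulus and the convention is a
single κ); each boundary is box-constrained to the interval between its
two adjacent category centroids, parameterized as a fraction of that
interval, with κ optimized on a log scale. Three L-BFGS-B starts
(centroid-interval midpoints plus two deterministically jittered
restarts), NLL tolerance 1e-8; non-convergence is flagged in the result,
never silent. Rotation equivariance and NLL-optimality against the true
generating parameters are enforced by tests.

The staircase estimator reads "step decreased by one fourth per reversal"
multiplicatively (new step = 0.75 × old): an additive −1° would hit zero
within four reversals; the step is floored at 0.25°. The reversal point is
the stimulus shown on the trial where the response direction changed
(conventional bookkeeping, recorded before the post-reversal move), and
interleaving is strict round-robin — the design says only "interleaved".
Staircases with fewer than two reversals are dropped from the estimate
with a warning.

Simulated categorizers default to a six-category model with boundaries at
the reported across-observer mean locations (pink-orange 21.1°,
orange-yellow 56°, yellow-green 78.1°, green-blue 168.1°, blue-purple
256.6°, purple-pink 300.3°) and κ = 10, which yields measurement noise of
roughly 18° SD — enough to produce the boundary-adjacent confusions the
cleaning and fitting stages must handle.

## Statistics

Paired two-sided t-tests between conditions (matched by observer),
Bonferroni correction min(1, m·p) with the family size configurable
(the original family sizes per test family are not recoverable), and
Pearson correlations across observers within condition among bias,
threshold, and the two fitted category boundaries nearest the target.
Zero-variance inputs are flagged as degenerate, not raised. Linear mixed
models are deliberately out of scope; the fit table exports in long format
for external LMM software.

## Problem sizes and determinism

Simulation-based checks use ≈10⁴ trials per condition for bias/threshold
recovery (PSE standard error ≈0.1° at that size), 50 replicate fits for
boundary-model recovery, and 200 seeded runs for staircase unbiasedness —
sizes at which the Monte Carlo error is an order of magnitude below every
tolerance tested. All randomness flows through `numpy.random.Generator`
seeded per run; schedules, response logs, and pipeline CSV outputs are bit
reproducible given (config, seed).

## Known limitations

* The observer models hue only; lightness/chroma variation, rendering,
  and display calibration are out of scope.
* The boundary model assumes stable boundaries and homogeneous von Mises
  noise around the circle; κ is shared across categories.
* The cleaning rule's "main group" can be ambiguous for categories used in
  two widely separated regions; ties are broken deterministically (span,
  then count).
* With 11 levels spanning ±20–35°, thresholds much above ~20° fail the
  PMF validity rule by construction — matching the analysis convention,
  but it means very noisy observers are excluded rather than estimated.
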