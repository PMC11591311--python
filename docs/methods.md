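# Methods

This note documents the models, conventions and numerical choices
behind the package, in the order data flows through the pipeline.

## Body rhythm

Raw input is 50 Hz tri-axial acceleration near the upper body. Per
10-second window the Euclidean norm's *mean crossings* are counted and
converted to Hz as `crossings / (2 × window seconds)`; the per-minute
body rhythm (BR) is the mean over the minute's available windows.

Conventions that the crossing count needs and that a sensor datasheet
would not settle:

* **Crossings-to-Hz divisor.** A sinusoid crosses its mean twice per
  cycle, so dividing by `2 × window seconds` makes a pure f-Hz signal
  read f Hz, which is what places everyday activities on the 0–4 Hz
  interpretive bands. The divisor is a module constant
  (`accel.CROSSINGS_PER_CYCLE`).
* **Samples exactly at the mean** (common on quantized sensors) are
  skipped: a crossing is counted when the nearest non-mean samples on
  either side have opposite signs. They neither create nor absorb
  crossings.
* **Partial minutes** are valid: BR is the mean over the 1–6 windows
  present, and a window is valid with ≥ 2 samples. Minutes with no
  data are absent from the series, never zero-filled; wear time is
  exactly the set of minutes with BR present.
* Boundary effects make a finite window lose up to one crossing, so a
  recovered frequency can sit 1/(2×10 s) = 0.05 Hz below truth; the
  frequency-recovery tests use that tolerance.

No gravity removal or band-pass filtering is applied: the statistic is
defined on the raw norm about its own window mean, which already
removes the DC (gravity) component per window.

## Episodes and exclusions

Directed detections (observer, detected, minute) are collapsed with a
**union rule** — a minute is active for a pair if either direction was
recorded — because missed detections are misalignment errors and
requiring both directions would double the miss rate. Same-pair active
minutes separated by gaps **strictly less than 5 minutes** are merged
into one episode. Merged episodes keep only the observed minutes; the
gap minutes are not back-filled into the interaction window (BR there
is unobserved interaction-wise, and back-filling would dilute the
engagement statistic). A `fill_gaps` flag restores the alternative
reading.

Participants with **< 5 h wear or < 1 h total interaction time** are
excluded, with strict inequalities (4.9 h wear is out), and every
episode involving an excluded person is dropped.

The `merge_fraction_report` diagnostic is the fraction of within-pair
adjacent events whose separating interval is < 5 minutes, where an
event is a maximal run of consecutive active minutes and the interval
is the minute-index difference the merge rule itself thresholds. Other
definitions (per record rather than per event pair) are possible; this
one is documented and tested.

## Physical engagement

For participant *i* of episode *k*:
`PE_i(k) = mean(BR_i, T_k) − mean(BR_i, T̂_k)`.

* **Window extension.** Body rhythm rises ~10 minutes before and after
  interactions (approach, greetings, badges acquiring each other
  late), so T_k is the episode's minutes plus `[start−10, start)` and
  `(end, end+10]`.
* **Shifted baseline.** T̂_k is the 30-minute window shifted before the
  extension: `[start−40, start−10)`, half-open, minute-indexed.
* **Day clipping.** Both windows are clipped to the day of the episode
  start; an overnight gap must not leak into a baseline. Within the
  day, minutes without BR simply drop out of the means.
* **Partner-free baselines.** While any episode's baseline contains
  minutes of an earlier same-pair episode, the two are merged (union
  of minutes) until a fixpoint. Interactions with *other* partners are
  left in the baseline — removing them would discard most baselines in
  a busy office — and are instead counted per record as a
  contamination diagnostic (mean ≈ 2.5, median 0 other-partner records
  per baseline under the default synthetic configuration).
* **Minimum data.** A record requires ≥ 5 baseline minutes and ≥ 1
  interaction minute with BR present; these floors are free parameters
  (the statistic is undefined on empty windows, and 5 baseline minutes
  keeps single-minute baselines from dominating). PE may be negative;
  there is no truncation.

PE is exactly shift-invariant (BR → BR + c) and scale-covariant
(BR → aBR maps PE → aPE); both are enforced by tests to 1e−9.

## CES-D

20 items scored 0–3; the four positively phrased items (standard
instrument positions 4, 8, 12, 16) are reverse-scored (3 − raw) before
summing to 0–60. Persons with missing or out-of-range items are
dropped by default. Cronbach's alpha uses the definitional variance
formula with n−1 denominators and is cross-checked against an
independent implementation in the tests.

## Statistics

* Correlations are Pearson with two-tailed p (Spearman duplicates on
  request); only the paired t-test for the interaction rise is
  one-tailed (the hypothesis is directional: interactions raise BR).
* The paired t-test handles the degenerate zero-variance-of-differences
  case explicitly (p = 0, 1 or 0.5 by the sign of the mean, with a
  warning) rather than returning NaN.
* **Kurtosis is non-excess** (normal = 3) in `distribution_report`,
  chosen for interpretability against the normal reference; most
  libraries default to excess kurtosis, hence the explicit flag.
* Bootstrap regression bands resample rows with replacement at the
  original size (default 1000 resamples), fit least squares per
  resample, and take percentile envelopes of the predictions on an x
  grid; degenerate resamples with zero x variance are redrawn. All
  bootstraps are seeded.
* Partner-number control restricts each employee's episodes to their
  top-N partners by episode count, ties broken by total interaction
  minutes then smaller partner id (determinism over elegance; the
  choice is immaterial at realistic contact heterogeneity).
  Per-organization summaries bootstrap employees *within* each
  organization and average the per-organization coefficients
  (resampling data rows); bootstrapping the organization-level
  coefficients instead is available behind a flag.
* Tertile grouping cuts the pooled selection-count distribution at the
  1/3 and 2/3 empirical quantiles (lower-value-at-ties) with *strict*
  membership inequalities, so ties at a cut fall to the lower group.
  That is what lets heavily tied counts produce the characteristic
  ordering high ≤ middle ≤ low instead of three equal groups.
* No multiple-testing correction by default (the analysis replicates a
  four-correlation battery as such); Benjamini–Hochberg columns are
  available via `stats.adjust_bh`.

## Synthetic data: what it emulates, and what it does not

Defaults are the study conditions: 450 employees in 10 organizations,
10 workdays of a contiguous 8-hour wear window, dyadic
within-organization contacts with a hub tenth of the population
initiating 3× the regular rate (2/day), geometric episode lengths with
mean 9 minutes, 20% per-direction detection dropout with dropped runs
capped below 4 minutes, baseline BR 1.10 Hz with 0.6 Hz within-person
spread, and a planted mean interaction rise of 0.26 Hz. Under these
defaults the pipeline sees ~10,700 episodes, ~28 distinct partners per
person, a ~40% short-interval merge fraction, and per-record PE
standard deviation ≈ 0.5–0.6 Hz — all in the neighborhood the study
reports.

Structure worth knowing when interpreting test results:

* **Noise model.** BR = person baseline (between-person SD 0.3 Hz) +
  AR(1) minute noise (φ = 0.9, stationary SD 0.6 Hz), clipped at 0.
  The high persistence is what gives window *means* realistic spread;
  white minute noise would make 30-minute means implausibly precise.
  Clipping introduces a small (< 0.01 Hz) upward bias in window means
  that largely cancels in PE.
* **Rise placement.** The planted rise covers the episode minutes
  *plus* a ±10-minute margin, mirroring the pre/post-interaction
  elevation the window extension exists to capture. With the rise
  confined to detected minutes the extension would mechanically dilute
  every recovered effect by ~3×, contradicting the phenomenon being
  modeled.
* **Interpersonal coupling.** Person i's rise in an episode with j is
  `δ + c_partner · z_j` (+ optional own-state term, optionally
  hub-only), with z latent depressive severity ~ N(0, 1). CES-D items
  are a one-factor discretization of z; the factor loading that makes
  the *discretized* items hit a target mean inter-item correlation is
  computed exactly from bivariate-normal rectangle probabilities, so
  an inter-item r̄ of 0.25 yields the Spearman–Brown alpha of 0.870 by
  construction, not by tuning.
* **Coupling calibration.** The coupling producing a target population
  engagement × partner-depression correlation is found by a seeded
  pilot simulation and the closed-form inversion of
  r(c) = cA/√(c²A² + B); calibration seeds are disjoint from
  evaluation seeds.
* **Mechanical mirror.** Because the coupling acts on the *rise* of
  the person facing a depressed partner, it also induces a strong
  partner-PE × self-DS correlation (the partner's PE directly encodes
  the ego's severity, with little averaging noise). The generator
  reproduces the study's target self-PE × partner-DS magnitude and the
  self/partner asymmetry; it does not attempt to match the relative
  magnitudes of all four correlations, which in real data reflect
  mechanisms (measurement resolution, individual differences) the
  one-slope model does not contain.
* **Not emulated:** multi-party meetings (episodes are strictly
  dyadic; overlapping dyads appear only through scheduling), infrared
  physics and geometry, raw acceleration at scale (a small-sample
  generator exercises the accel path), intra-day wear gaps, day-type
  or circadian structure, and any causal contagion dynamics. Passing
  tests therefore certify the *pipeline's* correctness and the
  recoverability of planted effects at realistic noise — not that real
  workplaces behave like the generator.

Same-pair episodes are scheduled ≥ 9 minutes apart so that detection
dropout (which can only shorten episodes at the edges) can never make
gap merging fuse two distinct true episodes; interior dropped runs are
capped below the 4-minute repair limit and at least one minute per
episode always survives. This makes "merged episode count = true
episode count" an exact invariant used as an oracle test.

## Problem sizes in tests

Oracle-equivalence and algebraic tests run on 500–1000 random
instances. Monte Carlo calibrations use scaled-down cohorts (80
employees, 2 organizations, 3 days) for replicate counts of 100–600,
and the full 450-employee configuration for the 5-seed rise detection,
the 50-replicate coupling recovery, and the end-to-end smoke run;
these sizes give standard errors comfortably inside the asserted
bands while keeping the default suite in the minutes range.

## Known limitations

* Engagement records of one person across episodes are not
  independent (overlapping windows, shared baselines); the paired
  t-test and correlations treat them as exchangeable rows, exactly as
  the replicated analysis does. The type-I calibration tests verify
  empirically that this leaves rejection rates near nominal under the
  generator's dependence structure.
* The baseline-integration fixpoint is implemented as deterministic
  first-found merging; merge order could in principle matter for exotic
  episode streams, and the oracle tests cover randomized streams to
  guard the implemented order.
* `exclusion_filter` needs wear tallies from BR presence; with raw
  detection logs only, wear time must be supplied externally.
* The 38.8%-style merge-fraction diagnostic is defined per adjacent
  event pair; a per-record definition would give different numbers.
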