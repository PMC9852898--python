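# Methods

`nwlchoice` re-implements, as a tested pipeline, the computational chain of
a mouse-tracking food-choice experiment in which participants choose between
pairs of food images under three instruction-induced eating contexts
(healthy, typical, unrestricted), first without and then with front-of-pack
nutrient warning labels (NWL) displayed. This note documents the models, the
synthetic-data generator that stands in for the (non-public) participant
data, the numerical choices, and the limits of what the test suite shows.

## Decision model

Choice and response time in each trial are modelled as a one-dimensional
diffusion with unit diffusion coefficient. Evidence `X(t)` starts at
`beta * alpha` and accumulates with drift `delta` until it is absorbed at
`alpha` (healthy choice, upper boundary) or `0` (unhealthy choice); the
observed response time adds a non-decision component `tau` (encoding +
motor). Parameters per participant × context × label condition:

| symbol  | name               | units        | bounds in fitting |
|---------|--------------------|--------------|-------------------|
| `alpha` | boundary separation| evidence     | [0.2, 6]          |
| `tau`   | non-decision time  | s            | [0, min RT − 1 ms]|
| `beta`  | bias (start point) | fraction     | [0.02, 0.98]      |
| `delta` | drift rate         | evidence / s | [−8, 8]           |

The first-passage density is evaluated with the dual series
representation — a small-time expansion over image charges and a large-time
sine series — choosing per time point whichever branch needs fewer terms,
truncated at absolute error 1e−10. Two analytic identities serve as
self-checks throughout the tests: normalization (the two defective
densities integrate to 1) and reflection (upper density at `(delta, beta)`
equals lower density at `(−delta, 1 − beta)`). The absorption probability
at the upper boundary has the closed form
`P = (1 − exp(−2·delta·alpha·beta)) / (1 − exp(−2·delta·alpha))`
(`beta` in the zero-drift limit), and the unconditional mean decision time
follows from the optional-stopping identity
`E[T] = (alpha·P − alpha·beta) / delta`.

Fitting maximizes the joint Wiener likelihood with bounded Nelder–Mead from
five dispersed starting points (the first data-driven, the rest spread over
the bounds with seeded jitter); `tau` is bounded just below the minimum
observed RT so the likelihood stays finite. Censored (deadline) trials are
excluded from the likelihood with a logged count; the response deadline is
rarely binding at the default parameters (<0.1% of trials), so no explicit
censoring term is included. Fits with a parameter within 1e−3 of a bound
are flagged `at_bound` (this is how all-healthy degenerate conditions
surface) rather than rejected.

### Trial simulation

Trials are simulated by Euler–Maruyama with step `dt = 1e−3` (1e−4 in the
density validation) plus a Brownian-bridge absorption test each step: given
the pre- and post-step positions, the path is declared absorbed with the
bridge crossing probability `exp(−2·(a−x0)·(a−x1)/dt)` (upper; analogously
for the lower boundary). This removes the `O(sqrt(dt))` boundary bias of
the plain scheme, which would otherwise be of the same order as the
validation tolerance (Kolmogorov distance < 0.01 against the series
density at 1e5 samples).

## Parameter-recovery validation

Per condition, the individual fits define a multivariate normal population
(sample mean and covariance over `(alpha, tau, beta, delta)`; covariance
repaired to PSD by eigenvalue clipping at 1e−10 when needed, flagged
degenerate). The Monte-Carlo procedure draws parameter sets from that
population (default 1,000), simulates 128 trials from each (both defaults
configurable), refits with the same settings, and then:

* flags empirical parameters outside the central 95% of the recovered
  marginals (two-sided reading of a 5% tail mass, with one-sided readings
  selectable; empirical quantiles use linear interpolation), and
* reports the Pearson correlation between generating draws and their
  refits per parameter. The draw-vs-refit pairing is the headline (it is
  the only pairing that measures whether generated parameters come back);
  a refit-vs-source comparison is available through the stored tables.

Draws that land outside the valid region are clamped to the boundary and
counted rather than redrawn, preserving the stated draw count. Calibration:
when the population is well specified and each draw is refit from 1,000
trials, the recovered distribution essentially reproduces the source
distribution, so about 5% of (fit, parameter) cells are flagged; the
acceptance check requires < 10%.

## Trajectory metrics and quality filters

Paths live in a normalized space: start button at the origin, response
images at `(−1, 1.5)` and `(+1, 1.5)` (the mouse-tracking-literature
convention; it makes the area measure unit-free). Right-choice paths are
reflected about the vertical axis, an involution that makes curvature
side-invariant. Per trial:

* **AUC** — signed area between the path and the straight line from its
  first to last sample, by trapezoidal integration of the perpendicular
  deviation over the along-chord coordinate (algebraically the shoelace
  area of the path-plus-chord polygon). Deviation away from the chosen
  side counts positive; the absolute-area reading is a switch
  (`signed_auc=False`). AUC scales as `c²` under coordinate scaling.
* **y-axis crossings** — strict sign changes of `x(t)` about the start
  abscissa, counted from the first movement sample (displacement > 0.02
  normalized units); samples exactly on the axis are bridged.
* **initiation time / RT** — start-press to first supra-threshold movement
  / start-press to click; a path that never moves is flagged rather than
  erroring.
* **sampling rate** — `(n − 1) / (t_last − t_first)`.

Exclusion rules (any rule fires ⇒ trial excluded, all evaluated in one
pass): sampling rate < 10 Hz; initiation time, AUC, or RT strictly greater
than the participant's mean + 3 SD (moments computed per participant over
that participant's rate-passing trials across the whole session — a
stability choice; per-context baselines can be injected through the
`baselines` argument); ≥ 3 axis crossings; fewer than both pair images
recognized (a missing recognition flag counts as unrecognized).
Participants with fewer than 2 rate-passing trials have undefined SDs;
their trials are retained by the 3-SD rules and counted in a warning
field. Computing thresholds once on the unfiltered base set makes the
filter order-independent and idempotent.

## Stimulus design

Each context inventory is drawn by stratified sampling without replacement
from the image pool: 32 images for the healthy context (8/6/8/10 per NWL
count 0–3), 29 for typical (7/6/7/9), 33 for unrestricted (8/6/8/11), 94
in all, with no image shared between contexts. A choice sequence shows 15
pairs for each of the six unordered NWL-count combinations (0–1, 0–2, 0–3,
1–2, 1–3, 2–3; the fifth follows from "six possible combinations" even
though enumerations often omit it) — 90 pairs per context — under two
constraints: an image must skip at least two pairs before reappearing, and
images with a given NWL count may not occupy the same side for more than
three consecutive pairs (runs of length 3 legal, 4 illegal, per side ×
count). Generation is rejection sampling with restart (shuffle the combo
order, place sides and images greedily, restart on a dead end, up to 1,000
restarts); a scanning validator implemented independently of the generator
audits the census, gap, and run rules. Within a combination, images are
drawn uniformly with replacement across pairs (15 pairs exceed the stratum
sizes), so per-image usage counts are random, not balanced.

## Synthetic-data generator

The generator is first-class, tested code; its defaults emulate the study
conditions: 128 participants, 3 contexts × 2 label blocks × 90 pairs (540
trials per participant), a 4-second response deadline, VAS ratings on
0–100, and contaminant trials exercising every filter. Within a context
the two label blocks reuse the same pair sequence (the design repeats the
same 90 pairs; their order in the second block is not specified, and reuse
keeps the sequence constraints trivially satisfied).

**Ratings.** Per participant and image, health/like/want ratings are
Gaussian draws (SD 12 VAS units, clamped to [0, 100]) around NWL-dependent
means: health 78/58/38/24 (monotone decreasing), like 68/56/50/63 and want
64/53/47/60 (U-shaped, minimum at 2 NWL) — the qualitative shape the
rating data show, with magnitudes chosen once as plausible VAS values.
Images are recognized with probability 0.91, which puts the fraction of
pairs with fewer than two recognized images near 17–18%, the scale of the
recognition exclusions in the study.

**Ground-truth diffusion parameters.** One parameter set per context ×
label condition (the published results are percentage contrasts on real
data, so the absolute values are free; these were fixed once to mirror the
qualitative orderings: healthy context largest bias and drift and shortest
non-decision time; labels raise drift and shorten non-decision time
everywhere but raise bias only in the healthy and typical contexts):

| context      | labels | alpha | tau  | beta | delta |
|--------------|--------|-------|------|------|-------|
| healthy      | no     | 1.6   | 0.35 | 0.62 | 0.90  |
| healthy      | yes    | 1.6   | 0.29 | 0.67 | 1.70  |
| typical      | no     | 1.6   | 0.40 | 0.57 | 0.60  |
| typical      | yes    | 1.6   | 0.36 | 0.62 | 1.15  |
| unrestricted | no     | 1.6   | 0.42 | 0.52 | 0.35  |
| unrestricted | yes    | 1.6   | 0.38 | 0.52 | 1.30  |

Trial-level drift adds a pair effect `N(0, 0.4²)` shared between the two
label blocks of a pair, plus `0.15 × (ΔNWL − 2)` where ΔNWL is the
within-pair label-count difference. The shared pair effect is what makes
reversal probabilities informative: without it, the second-block choice
would be independent of the first and the reversal probability would
collapse to the marginal healthy-choice probability under labels (> 0.9
everywhere). The ΔNWL slope gives the dose-response analysis a real signal.

**Paths.** A trial's path holds at the start (about 40% of the
condition's non-decision time), then follows a quadratic Bézier sweep to
the chosen corner whose control point is pulled toward the unchosen side
by `0.8 × conflict`, where conflict is `1 − |2p − 1|` and `p` the trial's
analytic healthy-choice probability — decisions near chance curve most.
Correlated positional jitter (smoothed white noise, SD 0.008) is added;
white noise would fabricate axis crossings. Sampling rates are
`N(60, 8²)` Hz, floored at 20.

**Contaminants.** Independent per-trial Bernoulli draws: low-resolution
trials (default 3.6%) are resampled at 4–9 Hz; multi-crossing trials
(2.4%) get a damped horizontal oscillation crossing the axis ≥ 3 times; RT
outliers (2%) are slowed far past the participant's typical range with the
path stretched to match; the unrecognized contaminant (default 0, the
recognition probability already carries that load) flips one pair image's
recognition flag. All carry ground-truth tags so filter recall is
measurable; the defaults sit at the scale of the corresponding exclusion
percentages reported for the real data.

What the generator does **not** emulate: real food photographs and their
perceptual properties; rating-driven drift (ratings and choices are
generated from the same NWL counts but not coupled trial-by-trial);
within-session fatigue or order effects; questionnaire instruments beyond
pass-through covariate columns; label-reading behavior within a trial.
Passing tests therefore show that the estimators recover what this
generative process encodes — not that the substantive findings would
replicate on new participants.

## Behavioral estimates

Mixed-effects logistic/linear models with Wald χ², estimated marginal
means and Tukey contrasts are deliberately replaced by direct proportions
and means with a participant-cluster percentile bootstrap (2,000 resamples
by default, seeded): the estimands — marginal probabilities and their
contrasts — are the same, and the substitution is recorded in the output
metadata. Reversal probability is the conditional proportion
`P(healthy with labels | unhealthy without) = |UH| / (|UH| + |UU|)`, an
exact identity with the decision-path census that the tests assert.
ΔAUC and ΔRT are `value_with_labels − value_without`, so negative values
mean the labels reduced curvature or sped the response; cell means are
adjusted for the no-label baseline by taking the intercept of an in-cell
regression of Δ on the globally centered baseline (raw mean when the
baseline is constant). Pairs missing one block are dropped with a logged
count. Covariates (age, sex, BMI, appetite, …) pass through for external
modelling but do not enter the headline estimates.

## Problem sizes and numerical choices

* Series truncation 1e−10; density floored at 1e−300 inside logs;
  impossible RTs (≤ tau) penalized with a large negative guard instead of
  −inf.
* Euler step 1e−3 for study simulation, 1e−4 for density validation, with
  bridge correction in both; decision-time horizon 20 s when no deadline.
* The test suite validates recovery on 100 conditions × 1,000 trials,
  calibration with 30 source fits × 120 recovery draws × 1,000 trials per
  draw, the sequence audit on 1,000 seeds, and the end-to-end orderings on
  a 50-participant study — sizes chosen to make each check statistically
  decisive on a single CPU. The recovery-improves-with-data property is
  checked at 32 vs 512 trials per draw over 4 replicates.
* Default recovery settings in the CLI remain 1,000 draws × 128 trials
  per condition.
* Every stochastic stage derives its generator from the master seed plus
  stage-name hashing, so runs are reproducible end to end and adding a
  stage never shifts another stage's stream.

## Known limitations

* The Nelder–Mead likelihood surface can hit bounds for degenerate
  conditions (e.g. all-healthy choices); such fits are flagged, and the
  population estimator ignores non-converged fits but keeps flagged ones.
* The bootstrap treats participants as exchangeable clusters; it does not
  model pair-level crossing of the two blocks, so CIs for reversal
  probabilities are mildly optimistic when pair effects are strong.
* Contaminant injection perturbs single trials; correlated artifacts
  (e.g. a participant's entire session at low resolution) are not
  modelled, which is why filter *recall* — not precision under realistic
  artifact clustering — is the tested quantity.
* With the default deadline and parameters, censoring is too rare to test
  deadline-heavy regimes; shorten `timeout` in the config to study them.
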