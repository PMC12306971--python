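# Methods

This note documents the models, conventions and numerical choices behind
`shadowtrial`, in the order data flow through the pipeline. Everything
stated here is computed by the package's tests or scripts; nothing is an
empirical claim about real flies beyond what the cited defaults encode.

## Kinematics

**Speed.** Per-frame speed is the Euclidean centroid displacement divided
by the frame interval, averaged into 10 ms bins on a fixed grid. At the
nominal 100 frames/s each bin holds exactly one frame, so binning is a
relabeling; the code handles other frame rates by true averaging. No
pre-smoothing is applied before binning.

**Trial windows.** Each shadow onset defines a 120-bin window
[−0.2 s, +1.0 s): 20 pre-stimulus bins and 100 post-stimulus bins. The
pre-window is half-open — the onset bin belongs to the post-window — so
v_pre (the mean of the 20 pre bins) is strictly pre-stimulus. Normalized
speed is speed − v_pre; its pre-window mean is 0 by construction. Trials
whose window is not fully covered by tracking, or which overlap a tracking
gap longer than 3 frames (shorter dropouts are linearly interpolated), are
marked invalid with a reason and excluded from profiles but never dropped
from attempted-trial counts.

**Acceleration.** Scalar acceleration is the central difference of binned
speed, d v/dt, so its sign separates speeding up from slowing down; vector
acceleration would conflate turning with speed change. Two signals are
kept per trial:

* `accel` — the per-bin central difference;
* `accel_smooth` (a_post) — the same derivative averaged with a centered
  11-bin (±50 ms, ~100 ms) window, shrinking symmetrically at the edges so
  the whole 1 s post-window stays scored. An even 10-bin window cannot be
  centered on a bin; the odd 11-bin window is the nearest centered
  equivalent.

**Which signal the classifier thresholds — a detection-bound argument.**
Averaging a derivative over a window of width w caps the result at
(speed change within w) / w. A complete stop from speed v therefore drives
a 100 ms-averaged acceleration to at most v / 0.1 s — only 80 mm/s² for a
fly walking at 8 mm/s — which can never reach the 200 mm/s² robustness
threshold from the typical 5–13 mm/s walking range, even though such stops
are plainly real. The classifier therefore applies the threshold to the
*per-bin* central difference, whose own bound is (speed change across two
bins)/0.02 s: a stop from 8 mm/s completed within ~40 ms registers at
≥ 200 mm/s², while a 10 mm/s speed gain spread over a second (10 mm/s²)
correctly does not. The smoothed a_post is reported as a descriptive
feature on every classified trial. Consequence: decelerations are
detectable only when the speed drops by ≥ 4 mm/s within ~20 ms — slow
walkers cannot produce a scoreable stop or slow-down, which matches the
empirical pattern that running and no-reaction dominate below 5 mm/s.

## Threshold classifier

Labels are exhaustive and exclusive over valid trials:

1. If |accel| never reaches 200 mm/s² in the post-window → **no_reaction**.
2. Otherwise the sign of the first threshold crossing is the "first
   reaction". Positive → **speed_up**.
3. Negative with v_pre > v_zero: **stop** if speed reaches ≤ v_zero before
   the first subsequent positive crossing (or window end), else
   **slow_down**.
4. Negative with v_pre ≤ v_zero (possible under noise): remapped to
   **no_reaction** — a stationary fly cannot meaningfully decelerate.

`v_zero = 0.5 mm/s` operationalizes "0 mm/s": centroid jitter makes exact
zeros unattainable. It is the single most sensitive constant in the
pipeline and is configurable everywhere it appears.

**Stop duration** is searched in the full-session 10 ms speed series, not
just the 1 s window: from the first post-onset stationary bin
(speed ≤ v_zero, required within 1 s of onset) to the first later bin
where speed > v_zero is sustained for ≥ 50 ms. The search is right-censored
at the next trial onset; censored durations are flagged, not discarded.
Because the binned series point-samples the underlying speed at the nominal
frame rate, the bin-index difference is an unbiased estimate with ±1 bin
quantization.

## Exploratory response typing

PCA (mean-centered, full SVD) reduces the 100-bin normalized post-stimulus
speed to 3 components; Ward-linkage agglomerative clustering in PC space is
cut at k = 4 by default, matching the four response types. Linkage, metric
and k are free choices — the clustering is a qualitative cross-check, not a
decision surface. On well-separated synthetic archetypes the clusters
reproduce the threshold labels almost perfectly (purity ≥ 95%, adjusted
Rand ≥ 0.7); on heterogeneous cohorts agreement degrades gracefully because
cluster boundaries track response *magnitude* (which scales with walking
speed) as well as type. That sensitivity of cluster boundaries to cohort
composition is precisely why group comparisons use the threshold
definitions.

## Speed conditioning and the virtual-fly null

The outer model bins v_pre into a dedicated stationary bin [0, v_zero),
2 mm/s bins up to 20 mm/s, and an overflow bin, and estimates per-bin label
frequencies from all pooled trials. Empty bins are flagged, never imputed.
The stationary bin cannot contain stop or slow-down mass (enforced).

The inner model simulates n = 3000 virtual flies per genotype: each draws a
speed with replacement from the genotype's empirical v_pre values (no
parametric fit) and a label from the pooled curve at that speed;
out-of-support draws use the nearest populated bin (logged).

**Chi-square comparison.** The default test is the 2 × 4 contingency
Pearson chi-square between observed and virtual label counts. Treating the
virtual proportions as exact (classical goodness-of-fit, available as
`method="gof"` and matching the textbook closed forms) is anti-conservative
by a factor ≈ 1 + n_obs/n_virtual, which is material when a genotype
contributes several hundred trials against 3000 virtual flies; the
contingency form accounts for the Monte-Carlo error and is calibrated at
any cohort size (verified: type-I rate 0.052 over 1000 null replicates at
520 observed trials).

## Group statistics

* Mann-Whitney U, two-sided; exact null for tie-free samples with both
  n ≤ 8, tie-corrected normal approximation otherwise. Percent change is
  computed on group means of per-fly values (configurable to medians);
  means are the default because reported effects are on mean speeds. This
  basis choice is the main reproduction risk when comparing against
  externally reported percentages.
* Dispersion: |log(var_A/var_B)| on median-centered values
  (Brown–Forsythe-style centering makes the statistic scale-free and
  location-robust); permutation p with the add-one rule
  (1 + #{perm ≥ obs})/(n_perm + 1), valid at any permutation count.
* Age trends: two-way ANOVA (genotype × age, type II, with interaction) on
  per-fly response proportions — reasonably robust to the non-normality of
  proportions — backed by per-genotype Kruskal-Wallis tests and
  adjacent-age Mann-Whitney post-hocs. Post-hoc p-values are reported
  uncorrected with an advisory threshold of 0.01.

## Synthetic data generator

The generator is first-class, tested code: it defines the conditions under
which every pipeline stage is validated.

**Locomotion.** Two-state (walk/pause) semi-Markov process. Bout durations
are shifted exponentials with a 0.3 s floor (walk mean 2.8 s; pause mean
set by the 30% stationary-time fraction); the floor prevents degenerate
sub-ramp bouts. Walking speed is log-normal across bouts (median 8 mm/s,
log-SD 0.45, spanning the 5–13 mm/s range where freezing is most frequent)
with an AR(1) fluctuation (SD 0.8 mm/s, τ = 0.2 s) while walking.
Spontaneous walk/pause transitions ramp over 0.2 s, keeping their
acceleration well below the 200 mm/s² threshold, and transitions that would
begin within 0.5 s before a shadow onset are deferred until just after it
so every trial has a well-defined baseline state. Real data offers no such
guarantee — passing tests show the pipeline recovers planted structure, not
that spontaneous behavior never mimics a response.

**Arena.** The path is folded into the 52 × 5 mm tunnel. Folding a
straight path shortens the within-frame displacement at a wall, which
would fabricate a deceleration spike; the lost distance is therefore
redirected into the transverse component (the fly turns the corner at
speed), preserving ground speed through reflections. Heading flips with
probability 0.35 per walk bout plus a small AR(1) wobble.

**Planted responses.** At each onset the generator measures the true v_pre,
draws a label from the genotype's configured speed-conditioned curve, and
injects the motif after a 0.2 s latency: ramp to 0 at 600 mm/s² held for a
log-normal stop duration (median 0.4 s, log-SD 0.6, clipped to
[0.1 s, 5 s]); ramp to a floor of max(1.5, 0.35 v₀) held 0.3 s; or an
8 mm/s burst. Motif ends blend back to the baseline over 0.15 s (a
sub-threshold ramp). The commanded 600 mm/s² is 3× the detection threshold;
configured curves place stop mass only at ≥ 6 mm/s and slow-down mass at
≥ 8 mm/s, respecting the detection bound above. The stationary bin carries
no stop/slow mass by construction (a non-moving fly cannot stop).

**Tracking noise.** Additive Gaussian centroid jitter with marginal SD
0.05 mm, modelled as a slow AR(1) posture/centroid drift (τ = 10 s)
plus a 0.001 mm white component. The spectrum matters more than the
marginal SD: video-tracked stationary animals produce nearly identical
frames, so frame-to-frame error is far smaller than the marginal error.
(A purely white 0.05 mm jitter at 100 Hz would imply ~7 mm/s apparent
speed for a motionless fly — inconsistent with any working stationarity
threshold.)

**Cohorts.** Default 13 flies per genotype (one arena load). Each fly gets
an independent schedule and session from a spawned child of the master
seed; the manifest records every child seed. (In the physical assay all 13
tunnels share one schedule; independent schedules are statistically
equivalent for all implemented analyses and simplify per-fly reproduction.)

## Validated properties (test suite)

With the defaults above, `tests/test_acceptance.py` verifies end to end:

* mean ITI of 10,000 generated schedules within 1% of 52.2 s;
* planted-label recovery ≥ 99% noise-free and ≥ 90% at default jitter
  (13-fly cohorts, ~520 trials each);
* classifier exhaustiveness/exclusivity, the stationary-fly constraint and
  the sub-threshold ⇒ no-reaction implication on 10,000 randomized traces;
* stop durations within 10 ms of planted values in ≥ 90% of noise-free
  stop trials (30 ms at default jitter, allowing for noise-shifted
  crossings);
* virtual-fly chi-square: type-I rate within [0.03, 0.07] over 1000 null
  replicates; power ≥ 95% against a half-strength stop→no-reaction curve
  shift;
* Mann-Whitney agreement with exhaustive enumeration (n ≤ 8); dispersion
  permutation test type-I within [0.03, 0.07] and p < 0.01 in ≥ 95% of
  replicates at variance ratio 10 (n = 50/group).

Problem sizes (cohorts of 13–40 flies, 1000 Monte-Carlo replicates,
999 permutations per test) were chosen so the whole suite runs in well
under a minute on one core while leaving the binomial error of every rate
estimate small against its acceptance band.

## Known limitations

* The classifier's detection bound makes stops below ~4–6 mm/s walking
  speed unscoreable by construction; analyses conditioning on v_pre
  inherit this.
* Stop-duration censoring is flagged but not modelled (no survival
  analysis).
* The generator does not emulate grooming, wall-following postures,
  multi-fly interactions, or jump/flight (physically excluded by the
  tunnel height), and its noise model is stylized; transfer of validated
  performance to real recordings depends on tracker quality.
* Percent-change effect sizes depend on the mean-vs-median basis choice
  documented above.
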