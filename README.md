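# shadowtrial

Trial-based analysis of fruit-fly escape responses to predator-mimicking
passing shadows.

In the assay this package analyses, single flies walk in shallow linear
tunnels (52 × 5 × 1.5 mm — too low to jump or fly) while an overhead screen
sweeps a dark "shadow" across the arena for 2 s, 40 times per ~40 min
session, at pseudorandom inter-trial intervals (exponential-like, mean
52.2 s). A camera tracks each fly's centroid at ~100 frames/s. The
scientific question is how threat responses — freezing, slowing, running —
depend on genotype, age and on the fly's own walking speed at the moment of
threat.

`shadowtrial` takes centroid trajectories plus the stimulus schedule and
produces:

1. **Stimulus-aligned kinematics** — speed in 10 ms bins on a
   [−0.2 s, +1.0 s] window around every shadow onset; the pre-stimulus mean
   v_pre is subtracted to give normalized speed; scalar acceleration
   a = dv/dt is computed per bin and also smoothed with a ~100 ms moving
   average (a_post).
2. **Threshold classification** of every trial into four response types.
   A reaction is *robust* if |a| reaches 200 mm/s² within 1 s of onset;
   otherwise the trial is **no reaction**. If the first robust reaction is a
   deceleration and the fly was moving (v_pre > v_zero = 0.5 mm/s), the
   trial is a **stop** when speed reaches the stationarity floor before the
   next robust acceleration, else a **slow down**; a first robust
   acceleration is a **speed up**. Stop durations are measured in the
   full-session speed series and right-censored at the next trial.
3. **Exploratory response typing** — PCA of the normalized post-stimulus
   speed (first 3 PCs) plus Ward-linkage agglomerative clustering, as a
   data-driven cross-check of the threshold taxonomy.
4. **Speed-conditioned response curves and a virtual-fly null** — the
   probability of each response type per pre-stimulus speed bin (outer
   model), and a Monte-Carlo cohort of n = 3000 virtual flies per genotype
   that draw speeds from that genotype's empirical v_pre distribution and
   labels from the pooled curve (inner model). A chi-square comparison of
   virtual vs observed label counts asks whether baseline speed alone
   explains a genotype's response mix.
5. **Group statistics** — two-sided Mann-Whitney U comparisons with
   percent-change summaries, a permutation test on dispersion
   (|log variance ratio| of median-centered values), and a genotype × age
   two-way ANOVA with Kruskal-Wallis and adjacent-age post-hocs.
6. **A synthetic-data generator** — run-and-pause locomotion in the tunnel
   with planted, speed-dependent responses and full ground truth (labels,
   latencies, stop durations, v_pre), used to validate every stage of the
   pipeline.

## Worked example

Simulate a control-like and a slowed, less reactive "parkin-like" cohort
(13 flies each, 40 trials per fly), classify every trial, and run the
group-level analyses:

```python
import shadowtrial as st
from shadowtrial.synthetic import control_like, parkin_like, generate_cohort

cohort, _ = generate_cohort(
    {"control": control_like(), "parkin": parkin_like()}, seed=42)
trials = st.classify_cohort([(ses, sch) for ses, sch, _ in cohort])

curve = st.build_curve(trials)
print(curve.to_frame().iloc[4:8].round(3).to_string(index=False))

per_fly = trials[trials["valid"]].groupby(
    ["fly_id", "genotype"], as_index=False)["v_pre"].mean()
res = st.compare_groups(
    per_fly.query("genotype == 'control'")["v_pre"],
    per_fly.query("genotype == 'parkin'")["v_pre"],
    metric="pre-stimulus speed", labels=("control", "parkin"))
print(f"speed: {res.percent_change:+.2f}% ({res.direction}), "
      f"U={res.statistic:.0f}, p={res.pvalue:.2e}")

null = st.run_virtual_fly_test(trials[trials["genotype"] == "parkin"],
                               curve, "parkin", seed=1)
print(f"virtual-fly null [parkin]: chi2={null.statistic:.2f}, "
      f"df={null.df}, p={null.pvalue:.3f}")
```

Output:

```
 bin_lo  bin_hi   n  p_stop  p_slow_down  p_speed_up  p_no_reaction
    6.0     8.0 170   0.347        0.006       0.212          0.435
    8.0    10.0 128   0.367        0.172       0.172          0.289
   10.0    12.0  63   0.444        0.143       0.048          0.365
   12.0    14.0  32   0.469        0.188       0.000          0.344
speed: -27.98% (decrease), U=164, p=5.09e-05
virtual-fly null [parkin]: chi2=5.06, df=3, p=0.167
```

The curve rows show, for four walking-speed bins (mm/s), how the
probability of each response type shifts with pre-stimulus speed — stopping
grows with speed while speeding up fades, as it must: a fly can only be
scored as decelerating if it was moving fast enough for the deceleration to
register. The Mann-Whitney comparison recovers the planted ~25% walking-speed
deficit of the parkin-like cohort (−27.98% in this draw, p ≈ 5e-5 at 13
flies/group). The virtual-fly test then asks whether the parkin response
mix differs from what its slower walking alone predicts; at this cohort
size the residual difference is not significant (p = 0.167).

There is also a CLI for file-based workflows:

```bash
shadowtrial simulate --n-flies 13 --seed 3 --out sim/
shadowtrial run --tracking tracking/ --schedule schedule.csv \
    --metadata metadata.csv --out results/
shadowtrial compare --trials results/classified_trials.csv \
    --metric speed --groups control,parkin --dispersion --virtual-null
```

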