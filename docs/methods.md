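# Methods

This note records the models, defaults and numerical choices behind
`gaitpark`, and what the synthetic tests do and do not establish.

## Signal model and preprocessing

A trial is a uniformly sampled (default 100 Hz) pair of per-foot total
vertical ground-reaction forces plus the 16 individual sensor channels.
Forces are physically non-negative; negative readings are sensor noise
and are clipped to zero at ingestion (the count of clipped values is
kept in the recording metadata).

Preprocessing has three steps:

* **End trimming** (default 20 s per end) discards gait initiation and
  termination. The default matches the protocol the target datasets
  were collected under (2–5 min walks).
* **Exclusion intervals** excise walkway turn-arounds. Turns were
  marked manually in the source protocols, so exclusion is
  caller-driven; `propose_turn_intervals` offers a stride-time outlier
  heuristic (> 3 scaled median absolute deviations, padded 0.5 s,
  merged) that *proposes* intervals for review and is never applied
  silently. Surviving segments become separately indexed blocks; no
  computation bridges a cut.
* **Median filtering** (default 10 samples) of the two total-force
  channels suppresses swing-phase fluctuation spikes. The even window
  is centred with left bias (5 samples before, 4 after) and defined as
  the mean of the two middle order statistics; edges shrink the
  window. This definition is deterministic but, unlike an odd-window
  median, produces one intermediate value per step edge and is
  therefore not idempotent at even widths — users wanting a
  conventional selector median should set the window to 11. Filtering
  is applied per block. Whether the filter should be centred or causal
  was an open choice; centred introduces no group delay, which keeps
  event times unbiased.

## Segmentation

No detection rule is canonical for total-force stance/swing splitting,
so the rule here is an explicit engineering choice: stance is force at
or above τ, with τ = 2% of the 95th per-block force percentile
(body-weight invariant) or an absolute level in Newtons. Phases
shorter than `min_phase_s` (default 0.05 s) are merged into their
neighbours, shortest first, which absorbs brief dropouts and residual
swing noise; leading/trailing incomplete phases are dropped so duration
statistics are unbiased. Detection is validated closed-loop: on
rendered synthetic signals every retained event matches ground truth
within one sample period, with either the double-peaked or a square
stance profile (the rule must not depend on stance shape).

Cycles are anchored on left heel strikes; the right cycle whose onset
falls inside a left cycle is its pair. Per cycle, the short-swing
value is the smaller of the two feet's swing times and the long-swing
the larger (`per_cycle` mode). The literature on the asymmetry
statistic can also be read as fixing one "short-swing foot" per record;
that `fixed_foot` mode (foot with the smaller mean swing) is a config
switch. Per-cycle min/max is the default because it is deterministic
and symmetric under foot relabelling. Double support is computed by
exact interval intersection of the left stance interval with the right
stance intervals inside the cycle, expressed as % of that cycle's
stride; a sampling-grid brute force is the test oracle.

An optional physiologic stride filter (preset 0.4–2.5 s) is off by
default: fidelity first, robustness opt-in. Dropped-cycle counts are
always recorded.

## The 19 features

`f1–f6`: CV (100·σ/μ, sample σ with n−1) of swing %, swing time and
stride time, left then right foot. `f7/f8`: CV of the short/long-swing
series. `f9` = 100·|ln(f7/f8)|. `f10–f15`: means of the same six
series. `f16`: mean double-support %. `f17/f18`: mean short/long
swing. `f19`: gait asymmetry — by default the *per-cycle*
100·|ln(ssw_i/lsw_i)| averaged over cycles; the ratio-of-means variant
100·|ln(f17/f18)| is available as `ga_mode="ratio_of_means"`. The
averaged reading follows the feature's published description; note the
two differ under cycle-level noise (Jensen: the per-cycle average is
≥ the ratio of means), which is visible in the README example.

A feature whose inputs are unavailable (f16 from interval-only data)
or undefined (f9 when either CV is zero) is NaN-flagged, never zeroed.
One feature vector is computed per preprocessed trial, pooling all
retained blocks; subject-level pooling is a caller decision.

All 19 formulas are pinned to an independently written brute-force
recomputation on 1,000 random stride tables and to hand-evaluated
cases (CV[1.0, 1.2] = 12.856%, GA(0.38, 0.40) = 5.129%).

## Feature selection

Relevance is mean Gini impurity decrease across a 100-tree bootstrap
forest (√n feature subsampling per split, unlimited depth), normalized
to sum to one; ties break by feature id; rows are canonically ordered
by record id before fitting so the ranking is invariant to table row
order given the seed. The selected set is the shortest ranked prefix
with cumulative relevance ≥ 0.80, or exactly the top k when a fixed
size is requested (both rules exist because a cumulative threshold and
a fixed cardinality can disagree). By default selection runs once on
the full table — mirroring per-dataset selection reported outside the
cross-validation loop — with a nested per-fold mode available for
leakage-free estimates.

Two behaviours worth noting under √n subsampling: a perfect predictor
does not absorb a majority of the relevance (root splits often cannot
see it; it still ranks first by a wide margin), and duplicating an
informative feature *raises* the pair's combined credit while diluting
each copy, because duplication doubles the signal's availability at
splits.

## Classification and evaluation

Seven models: K-NN (Euclidean; even-K ties broken by the single
nearest neighbour so predictions are deterministic), CART (Gini),
random forest, Gaussian naïve Bayes, SVM (linear or polynomial, degree
3, C = 1), 2-cluster K-means and a 2-component Gaussian mixture (full
or diagonal covariance, 5 EM restarts, seeded). Features are z-scored
with training-fold statistics only — the feature set mixes seconds and
percentages, and distance-based models are scale-sensitive.
Unsupervised models are fit per fold without labels; clusters map to
classes by the training-accuracy-maximizing permutation and the
held-out record goes to the nearest centroid / max-responsibility
component. Grid search (K-NN 2–10; forest 10–200 trees by 10)
maximizes LOOCV accuracy with ties to the simpler model.

Reported precision/recall are macro averages over the two classes,
with per-class values always emitted; F<sub>β</sub> is computed from
the macro pair (β = 1 default). Zero-denominator per-class metrics
are flagged undefined and excluded from the macro mean. Confusion
matrices are emitted row-normalized (rows = true classes). Random
under-sampling reduces every class to the minority count, without
replacement, seeded.

## Synthetic generator

The generator encodes the statistical contrasts the analysis assumes:
class-dependent stride/swing means and CVs and left/right swing
asymmetry. Stride times are truncated normal (±4σ, positive) for
direct mean/CV parameterization — lognormal or gamma would serve as
well; the distribution is pluggable. Swing times are
`swing_fraction`·stride with per-foot factors exp(±a/200), making the
feet's swing ratio exp(−a/100) so the log-asymmetry statistic recovers
`a` exactly at zero CV, plus multiplicative swing-CV noise (swing <
stride enforced by resampling). Each foot's stride sequence is drawn
independently, so the half-stride phase offset between feet diffuses
over a long record; ground-truth double support is therefore defined
by interval intersection of the *realized* event times, which is also
what segmentation sees.

Rendering places a double-peaked stance profile (Gaussian bumps at
25% / 75% of stance, 1.10/1.05 × body weight, width 0.13·stance —
purely cosmetic, as the square-profile test enforces), zero-mean
clipped swing noise, optional quiet-standing pads and an irregular
half-loaded "turn" block with its true exclusion interval. The class
presets (healthy-like: stride 1.10 s, CV 2%, asymmetry 2%; PD-like:
stride 1.15 s, CV 5%, asymmetry 8%) are illustrative test conditions
consistent with the qualitative literature contrasts, not estimates of
any study population.

What the generator does **not** model: spatial pressure distribution
across the 16 sensors (rendered as fixed fractions of the totals),
kinematics, fatigue or drift within a trial, freezing episodes, and
any correlation structure between features beyond what the gait
timing model induces. Passing closed-loop tests therefore demonstrate
the pipeline's internal consistency and estimator calibration, not
clinical performance; published headline accuracies require the
original clinical recordings, which this package ingests but does not
ship.

## Problem sizes and determinism

Test and acceptance runs use 200-cycle records (a 2–5 min walk at a
1.1 s stride yields 110–270 cycles, so 200 is representative), 20–50
seeded replicates for closed-loop statistics, 100 replicates for
selection power and 40-record tables for the classifier benchmark.
Every stochastic component draws from `numpy.random.default_rng`
seeded from a single master seed; manifests record enough to
regenerate any artifact bit-identically.

Known marginal case: the selection null bound (no noise feature
reaching 0.25 relevance at 40 records × 19 features) sits close to the
null distribution's upper tail; individual seed streams can graze
0.26. The acceptance script reports the measured maximum rather than
a pass/fail.
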