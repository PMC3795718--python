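# Methods

This note documents the model implemented by `rsnr`, the choices made where
the design was genuinely open, and what the synthetic benchmark does and does
not establish.

## Data model

An `ExpressionDataset` is a genes × samples matrix plus a sample table
mapping every column to an experimental condition, a time point and a
1-based replicate index.  A condition is identified with its *set of
experimental factors* (e.g. `{cold, root}`); this set drives the rSNR
negative-set construction below.  Values are used as given — log scale is
typical for microarray data and the package never rescales; the fold-change
filter exposes an explicit `log_scale` flag instead of guessing
(`max/min ≥ f` on a linear scale, `max − min ≥ log2(f)` on log2).
Missing cells are rejected at load time rather than imputed.

Quantile normalization maps every column onto the mean order-statistic
distribution; ties within a column receive the mean of the reference values
their rank run spans.  With that tie convention the transform is exactly
idempotent only on tie-free columns, which is what the property test checks
(continuous data; ties are measure-zero).

## Transition profiles

A pair of time points (t_x < t_y) of one condition is summarized as a single
gene-indexed vector: the **DTP** `E(t_y) − E(t_x)` (expression change) or the
**MTP** `(E(t_x) + E(t_y))/2` (mean level); **TIMEPOINT** keeps the two raw
single-time-point profiles for a fairness comparison.  MTP ± DTP/2
reconstructs the original two profiles, which the tests assert exactly.

Replicate policy: replicates are averaged within each time point when
building *training* profiles (default); *test* profiles always use the single
drawn replicate.  A `replicate_policy="each"` variant enumerating one profile
per replicate combination exists for sensitivity checks.  Training profiles
are enumerated over **all** ordered pairs t_x < t_y of a condition's time
points by default; `pair_mode="consecutive"` restricts to adjacent pairs.
The all-pairs enumeration is the default because the training side of the
comparison is defined over every available transition, while test units are
always split into consecutive pairs.

Link profiles re-index any gene profile by scored gene–gene interactions
(STRING detailed-links dialect, integer confidence 0–1000): the value of a
link is the mean of its two genes' values.  Gene- and link-based selection at
a confidence cutoff keep, by construction, exactly the same gene set.

## The rSNR

For target condition k, the training data are split into the **positive set**
(k's training samples) and the **negative set** (training conditions whose
factor sets are disjoint from k's); conditions sharing ≥ 1 factor with k are
excluded from the calculation entirely, so that partially related conditions
can neither inflate nor deflate the extrinsic-variation estimate.  An empty
negative set is an error, not a NaN.

Per gene, with sample (n−1) standard deviations throughout:

- `SNR_pos = |μ_pos|/σ_pos` over the pooled positive values (all time points
  × replicates);
- per negative condition i, `m_i` = mean of the gene's values in i;
  `SNR_neg = |mean_i m_i| / sd_i m_i`;
- `rSNR = SNR_pos/SNR_neg`, identically `CV_neg/CV_pos`.

Absolute values make the score well defined on log-ratio data where means can
be negative; specificity is a magnitude notion and a sign flip must not
reorder genes.

**Aggregation axes.** The positive σ may alternatively be computed per time
point and averaged, and the negative side aggregated over per-time-point
means (`aggregation="per_timepoint"`).  Both readings are defensible — the
pooled/per-condition form treats the condition as one sample of values, the
per-time-point form weights the time grid evenly — so the pooled form is the
default and the other is one switch away.

**Degenerate quotients** are deterministic, never NaN: σ_pos = 0 with
cross-condition variation present gives +inf (a perfectly stable,
cross-variable gene is maximally specific; the sentinel sorts above all
finite scores, gene-id tie-broken); σ_neg = 0 gives 0 (no extrinsic
variation, uninformative — this rule takes precedence when both σ are zero,
since a globally constant gene is uninformative); μ_pos = μ_neg = 0 gives 0
with a warning.  Constant rows are detected exactly (axis-wise `np.std` can
return ~1e−15 on constant input, which would defeat the sentinels).

Baselines are one-vs-rest per condition inside the CV (class 1 = the target
condition's training samples, class 2 = the rest): the two-class
signal-to-noise statistic `|μ₁−μ₂|/(σ₁+σ₂)` and Welch's t
`|μ₁−μ₂|/√(σ₁²/n₁+σ₂²/n₂)`, both ranked by absolute value (both directions of
change are informative for selection; no p-values are attached because the
statistic is used only as a ranking score).  The random control draws a
uniform gene subset without replacement.

## Classification

1-nearest-neighbor by Pearson correlation.  Against condition k's training
profiles the correlation uses only k's selected genes (or all genes without
selection).  Each consecutive test pair casts one vote for the condition of
its most-correlated training profile; the majority wins, vote ties go to the
tied condition with the highest sum of its winning similarities, and residual
exact ties to the lexicographically first condition id.  Exact correlation
ties between training profiles resolve to the first profile in
(condition_id, time_pair) order.  Zero-variance vectors get a sentinel below
−1 so constant profiles can never be nearest neighbors; training profiles
whose selection leaves < 3 common features are skipped (error if all are).
In TIMEPOINT mode the two single-time-point test profiles are compared
against all training time-point profiles and the global maximum decides.

## Cross-validation

Time-course CV draws, per condition and fold, a test unit and a training
mask:

- **Scenario 2** (default, stricter): exactly 2 random time points, one
  random replicate each; *all* replicates of those time points are removed
  from training.  Conditions need ≥ 4 time points so their training data
  never empties; shorter conditions are skipped as test sources.
- **Scenario 1**: a uniformly random number k ∈ {2, …, T} of time points
  (the distribution is unspecified in the underlying design; uniform is the
  maximum-entropy choice), one random replicate each; only the test samples
  themselves leave the training data.

Defaults are 10 folds per condition per repetition; repetitions, seeds and
every switch live in `CVConfig`.  Selectors are fitted on the training mask
only — an invariant asserted by a test that shuffles test-only columns and
checks the fitted ranking is unchanged.  Static (normal/diseased) collections
use leave-one-experiment-out folds, each experiment contributing one MTP/DTP
profile as a separate database entry.

Accuracy is the fraction of correctly labeled test units; the result reports
the standard deviation both across repetitions and across folds, since either
may be meant by "error bars over repetitions" in this kind of design.
Query-vs-database evaluation computes, per query experiment, the correlations
with all remaining experiments (per-condition selections fitted without the
query), labels same-condition entries positive, and reports the mean
per-query AUC; the AUC uses the rank-sum formulation with ties counted ½,
equivalent to sweeping all cutoffs.  Undefined per-query AUCs (no positive or
no negative database entry) are excluded and counted rather than imputed.

## Synthetic data

The generator emulates the designs the method targets: a factorial condition
grid (default six single-factor conditions; presets shaped like a 9×2
stress/tissue time course with T=8 and 2 replicates, a toxicology course with
T=12 and ragged replication, and a 3-condition static normal/diseased
collection), a per-gene baseline `N(7, 1)` on an additive log-like scale, and
i.i.d. `N(0, noise_sd)` sampling noise.

Planted condition-specific genes follow the premise of the statistic: in
their own condition they sit `planted_shift` above baseline with small
within-condition sd (`planted_within_sd`); every other condition receives its
own mean offset drawn from `N(0, condition_spread_sd)`, constant across time.
The default effect sizes — `noise_sd = 2.0`, `planted_shift = 2.0`,
`planted_within_sd = 0.4`, `condition_spread_sd = 1.0` — place the data in
the regime the method is designed for: `noise_sd` (absorbing temporal
dynamics and replicate noise of non-specific genes, pooled across a
time course) exceeds the across-condition spread, so correlations over all
1000 genes are noise-dominated and selection is decisive, while the per-gene
CV contrast (0.4 vs 2.0 within condition) keeps markers individually
recoverable.  Under these conditions the package measures top-20 precision
≈ 0.95, and section-wise CV accuracy ordered bottom ≈ chance < random-200
≈ 0.65 < top-200 ≈ 1.0.

The interaction generator links pairs within one condition's planted set with
probability `link_p_signal` and other pairs at a background rate
`link_p_noise`, scores uniform over a configurable range.

**What the generator does not emulate:** probe effects, intensity-dependent
variance, batch structure, missingness, temporal autocorrelation or realistic
regulatory covariance between genes.  Passing tests therefore demonstrate the
correctness and the designed qualitative behavior of the method — not its
accuracy on any real compendium.

## Null calibration

With condition labels permuted (within every (time point, replicate) cell
across conditions, preserving the grid), classification should be at chance
1/N.  Two structural caveats, verified by measurement, matter for how this is
tested:

- Under **scenario 2** the test condition contributes fewer training
  transition profiles than the others (two of its time points are removed),
  so the permuted accuracy sits *below* 1/N by design.
- Under **scenario 1 with MTP** all samples share the per-gene baseline, so
  Pearson similarity is baseline-dominated; the held-out test replicate
  leaves the test condition's training profiles averaging fewer replicates,
  diluting its correlations — again a conservative (downward) bias, measured
  at ≈ 0.04 vs 1/6.

**Scenario 1 with DTP** cancels the shared baseline exactly and keeps
per-condition profile counts equal, so permuted labels are exchangeable and
chance is 1/N; the package measures ≈ 0.17 across independent permuted
datasets.  Because folds within one dataset reuse the same finite
label–value alignment, fold outcomes are correlated and the standard error is
estimated across independent datasets, not from pooled fold counts.  The MTP
null is additionally checked against the upper bound (no optimistic leakage).

## Numerical and bookkeeping choices

- Pearson correlations are clipped to [−1, 1] against rounding excursions.
- Rankings sort by descending score with lexicographic gene-id tie-break;
  +inf sentinels sort first; re-runs are bit-identical.
- Random draws everywhere use `numpy.random.default_rng` seeded from explicit
  configuration; CLI runs with the same seed are byte-identical.
- TSV round trips are exact (`float_precision="round_trip"` on read).
- Rank sections tile the descending ranking from the top in steps of the
  section size; a remainder shorter than one section at the bottom of the
  list is not evaluated.  The step-wise reduction grid is G, G−step, …, down
  to the smallest size ≥ 1; at n = G the rSNR and random settings coincide by
  construction.

## Known limitations

- The rSNR needs ≥ 2 negative conditions and ≥ 2 positive values; designs
  where every condition shares a factor with every other are rejected.
- Interaction-based selection treats links as undirected and does not
  recalibrate confidence scores.
- The classifier is strictly 1-NN with unweighted votes; k > 1, similarity
  weighting beyond tie-breaks, and other similarity measures are out of
  scope.
- Per-time-point aggregation requires ≥ 2 replicates at every positive-set
  time point and errors otherwise.
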