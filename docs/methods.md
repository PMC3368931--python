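# Methods

This note documents the models, parameters and numerical choices behind
`burstclust`, and what the synthetic-data experiments do and do not
demonstrate.

## Burst detection

The detector is a left-to-right scan over interval rules (all thresholds are
`DetectorParams` fields, seconds):

- a candidate opens at a spike preceded by ≥ `pre_silence` = 60 ms without a
  spike — the recording start counts as silence, otherwise the first burst
  of every file would be rejected unfairly;
- the candidate's second spike must follow within `second_spike_max` = 15 ms;
- spikes accrue while every ISI < `end_isi` = 30 ms and every pair of
  consecutive ISIs sums to ≤ `end_pair_sum` = 45 ms.  When the pair rule
  fires, the burst is terminated *before the first* of the two offending
  intervals; this keeps the in-burst rate at or above the ~33 Hz floor the
  single-interval rule implies;
- accepted bursts have ≥ `min_spikes` = 5 spikes (inclusive) and a span
  strictly greater than `min_duration` = 8 ms.

Rejected candidates are discarded, but their spikes still count against the
pre-silence requirement of later candidates — a conservative reading of the
silent-interval rule.  The pair rule is applied uniformly from the first
pair of ISIs onward; with a 15 ms first ISI and sub-30 ms successors the
first pair can never fire, so the convention is observationally neutral at
the default thresholds.

Stimulus association labels the burst nearest to each trigger onset within
±50 ms; a burst claimed by several triggers goes to the nearest (ties to the
earlier trigger), and all unassociated bursts are labeled `N`.  The window
accommodates the ~10 ms response latency and bursts whose detected onset
moves earlier because a background spike was absorbed into the burst.

## Spike-time metric

`vp_distance` is the classical two-train edit distance computed by dynamic
programming over spike indices (O(n·m)); insertions/deletions cost 1 and a
shift of Δt costs q·|Δt|.  Properties exploited by the tests: |n_a − n_b| is
a lower bound, n_a + n_b an upper bound; q = 0 degenerates to the count
difference; q → ∞ counts non-coincident spikes; shifting is preferred to
delete+insert exactly below 2/q.  The DP is numba-compiled; only costs are
returned, so equal-cost path ties need no canonical resolution.

Default q = 62.5 s⁻¹ is anchored to the calibration statement that one
insertion equals a 16 ms shift (1/0.016 s); it lies inside the 50–100 s⁻¹
band where class separability is near-maximal in the `q_separability`
analysis on synthetic data.  `scripts/acceptance.py` re-derives the 16 ms
equal-cost point numerically from the implemented metric.

`burst_shift_distance` minimizes over deleting k_a ≤ n_max and k_b ≤ n_max
initial spikes (cost 1 each, both trains — the operator is symmetric),
re-zeroing each remainder to its new first spike, and applying the plain
metric.  Deleting every spike of a train is admissible when n_max allows it
and costs the spike count.  Re-zeroing makes the comparison depend only on
the pattern relative to the (corrected) onset, which is what burst analysis
needs; it can violate the triangle inequality, so no test asserts metricity
for the burst-shift variant, and affinity propagation does not require it.
Default n_max = 2: pre-burst noise spikes are occasional, rarely more than
two; the budget is exposed as a parameter everywhere.

For `q_separability` the "noise only" separability is defined as the mean
noise-vs-stimulus pair distance minus the mean within-noise distance (the
whole-dataset and stimulus-only variants restrict both terms to the
respective subsets); equal-spike-count within-class means are computed per
stimulus class and then averaged unweighted across classes.

## Affinity propagation

Message passing follows the canonical responsibility/availability updates
on the similarity matrix s(i,k) = −d(i,k):

    r(i,k) ← s(i,k) − max_{k'≠k} [a(i,k') + s(i,k')]
    a(i,k) ← min(0, r(k,k) + Σ_{i'∉{i,k}} max(0, r(i',k)))   (i ≠ k)
    a(k,k) ← Σ_{i'≠k} max(0, r(i',k))

with damped updates (λ = 0.5 by default, the canonical choice for these
equations) and a **fixed 200 iterations with no early exit**, which makes
runs exactly reproducible.  Point i is an exemplar iff
argmax_k [a(i,k)+r(i,k)] = i, ties broken toward the lowest index;
non-exemplars are assigned to their most similar exemplar (the update
equations only identify exemplars; the assignment pass is standard
practice).  If no exemplar emerges a `ConvergenceError` carries diagnostics.

Preferences (diagonal similarities) are the median off-diagonal similarity
times a multiplier `p_mult` ∈ [1, 20]; since similarities are negative,
larger multipliers yield fewer clusters, monotonically over the tested
battery.  Independent zero-mean Gaussian noise of scale
10⁻⁶ × (off-diagonal range) is added per off-diagonal entry (asymmetry is
harmless to the algorithm).  The noise is not cosmetic: on exactly
symmetric inputs — e.g. two identical tight pairs — the message fixed point
ties every point's self-criterion at zero and exemplar identification
degenerates; the seeded noise resolves such ties reproducibly.

Dendrograms over exemplars use group-average (UPGMA) agglomeration via
`scipy.cluster.hierarchy`; heights are cross-checked against a brute-force
averaging oracle in the tests.  Silhouette values come from
`sklearn.metrics.silhouette_samples` on the precomputed distances
(singleton clusters score 0 by that convention).

## Labeling, entropy, confusion

Cluster labels maximize f_X(c)/f_D(c) over classes with nonzero dataset
frequency; ties break to the larger within-cluster fraction, then to the
lower class id with `N` last.  The ratio criterion avoids labeling
everything noise when noise bursts are several times more frequent.

Per-class homogeneity is H(X_c | L) = H(X_c, L) − H(L) in bits (0·log 0 = 0),
restricted to clusters containing at least one class-c burst.  Two
consequences worth noting: the value is 0 iff every considered cluster is
pure in X_c; and because the restriction changes the population, *splitting*
a cluster can raise the value when one part loses all its class-c bursts —
the usual "refinement never increases conditional entropy" theorem holds
only among splits whose parts both retain the class.  The tests assert
monotonicity in that regime.

Confusion matrices average class-frequency vectors unweighted: first over
clusters sharing an assigned label within a session, then over sessions in
which the label occurs.  Rows with no cluster anywhere are reported as NaN.
Across-session dispersion, where reported, is the per-class SD across
sessions (session count, not session×class, is the averaging unit).

## Cross-session matching and surrogates

Exemplar-to-exemplar burst-shift distances define the match; each source
cluster maps to the argmin target (many-to-one allowed, ties to the lower
id).  The null model replaces every burst by an inhomogeneous Poisson train
whose rate profile is the cluster's onset-aligned PSTH in raw 2 ms bins
(no smoothing; the profile extends to the longest burst in the cluster),
sampled by thinning a homogeneous process at the profile maximum.  Twenty
surrogates per cluster keep the Monte-Carlo standard error small relative
to the order-of-magnitude gap between match distances and baselines on
patterned clusters; surrogates are re-zeroed to their first spike before
the distance is taken, mirroring detected bursts.  Coincidence curves are
restricted to spikes inside detected bursts and reported in both directions
for Δ ∈ {1, 5, 10} ms.  Burst-shift distances are used throughout the
paired analyses for consistency; the plain metric is available via
`n_max=0`.

## Synthetic recordings

The generator is the package's test bed and defines its study conditions:

- **Background**: a dead-time renewal process (20 ms absolute dead time,
  hazard corrected so the realized rate matches the target) whose rate
  follows a 20-minute sinusoid, 12 Hz × (1 ± 0.4) ≈ 7–17 Hz.  The dead time
  reflects that in the emulated recordings sustained >33 Hz runs originate
  from acoustic events, which the generator models explicitly; a memoryless
  background at these rates would plant spurious bursts that belong to no
  ground-truth event.  Consequence: the non-burst background alone can never
  satisfy the detector (no ISI below 15 ms exists), which is what makes
  perfect precision a meaningful target.
- **Noise bursts**: Poisson event times at 0.4 Hz (four times the stimulus
  burst rate) instantiate one of 8 archetypes drawn once per library seed —
  half short patterned trains (6–12 spikes, ISIs 2.5–8 ms, span ≥ 14 ms),
  half long unstructured trains (up to 40 spikes, ~0.1–0.3 s, ISIs ≤ 14 ms).
  ISI caps are chosen so that losing any single spike (refractory collision
  or paired-mode thinning) cannot push a merged interval past the 30 ms
  termination rule: archetype detectability is robust to single-spike
  deletions.  Archetype diversity per night is not an estimate of anything —
  the count is a free knob.
- **Stimulus bursts**: each trigger (every 10 s, classes drawn uniformly
  from the configured set) evokes a burst with Gaussian latency
  (10 ± 2 ms) whose spikes sit on a 500 Hz grid inside the class's
  latency-shifted pulse epochs, plus per-spike Gaussian jitter (0.5 ms).
- **By-construction detectability**: every planted instance is jitter-
  redrawn (bounded retries) until it satisfies the detector rules with a
  small safety margin; planted events are rejection-sampled so no two
  planted bursts, and no noise burst and trigger window, overlap; background
  spikes are suppressed from 80 ms before each planted onset to 50 ms after
  its last spike.  These guards encode the premise that real bursts are
  detectable events preceded by silence — without them ground-truth labels
  would be ill-defined.
- **Pre-burst noise spikes**: with probability 0.1 one extra spike lands
  5–15 ms before a burst's first spike.  The upper bound is the detector's
  second-spike window: a noise spike further out would not be absorbed into
  the burst but would instead destroy its pre-silence, i.e. it would model
  an undetectable burst rather than the onset-contamination the burst-shift
  operator exists for.
- **Paired mode**: both preparations share the event sequence, base spike
  patterns and background stream; each applies its own per-spike jitter,
  and preparation 2 thins every spike with probability
  `sensitivity_offset` (default 0.1, chosen so the pooled clustering
  reproduces the roughly half-and-half preparation mixture and
  near-diagonal nearest-burst scatter that simultaneous recordings of this
  kind show; per-spike thinning is a blunt proxy for a ~5 dB threshold
  offset, and at 0.2 it instead shreds small patterns into
  preparation-pure "degraded" clusters).  The paired-mode pooled analysis
  is run at `p_mult` = 3: pooling doubles within-pattern variability, and
  archetype-level granularity needs a moderately coarser preference.
- A 0.5 ms refractory gap is enforced globally by dropping the later spike
  of any violating pair (real neurons cannot fire twice instantaneously).

**What passing tests show — and don't.**  The generator's bursts are
noiselessly planted patterns with independent Gaussian jitter; real
recordings contain overlapping bursts, amplitude-dependent latencies,
rate adaptation, electrode artifacts and non-stationary background, none of
which are modelled.  Perfect recall/precision and zero conditional entropy
on synthetic sessions therefore validate the *implementation* (rules,
metric, message passing, bookkeeping) under the stated statistical
structure, not the expected performance on field data.

## Problem sizes and determinism

Synthetic sessions in the test suite use 150–600 s durations (60–300
planted bursts, distance matrices up to ~300×300), 20 seeds for the
parameter-recovery battery and 2 seeds for the paired analyses — sizes at
which every stochastic claim is measured with comfortable margins while the
suite stays quick.  All randomness flows from named integer seeds through
`numpy.random.Generator` streams; there is no global random state, and
identical configurations reproduce recordings, clusterings and pipeline
artifacts bit-for-bit.

## Known limitations

- Repetitive burst *sequences* (rhythmic multi-burst motifs) are outside
  the model; bursts are treated as exchangeable units.
- The burst-shift operator deletes initial spikes only; trailing
  contamination is not compensated.
- Affinity propagation is run dense (O(n²) messages); sessions beyond a few
  thousand bursts need blocking or sparsification that the package does not
  provide.
- The conditional-entropy restriction to clusters containing the class
  makes values across clusterings with different cluster counts only
  loosely comparable (see the refinement caveat above).
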