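# Methods

## Records and extraction

Continuous pocket-phone monitoring is reduced to fixed-size movement
records.  Raw traces (time in seconds, x/y/z acceleration in g) are
linearly interpolated per axis onto a uniform 50 Hz grid spanning the
trace and clipped to the sensor range (±2 g by default); interpolation is
linear because nothing finer is warranted for 50 Hz kinematics and it
preserves peak locations.  Candidate events are local maxima of the
magnitude series ‖(x, y, z)‖ at or above 1.5 g.  Peaks closer than 6 s
are resolved greedily by descending magnitude (index as the deterministic
tie-break), so the dominant event in any crowded stretch survives.  Each
surviving peak yields a record: 51 samples per axis (±0.5 s inclusive)
with the peak at 0-based index 25.  Peaks within 25 samples of a trace
edge are skipped.  A cropped window is kept only if its center magnitude
is the window maximum and ≥ 1.5 g, so every record in a dataset satisfies
the same invariants regardless of origin.  Record CSVs store
`subject_id,label` plus 153 values at 10 significant digits; round-trips
are exact at that precision.

## Distance, novelty scores, kernel

The record distance is the Euclidean distance in the flattened 3×51
space: the root of the summed squared per-sample vector differences.  It
compares whole acceleration shapes rather than isolated peak features.

**NN.** The score of a query is its distance to the nearest ADL exemplar.
No self-exclusion is applied: a record that is itself an exemplar scores
exactly 0.

**k-NN distance and LOF.** When a query coincides with an exemplar
(object identity or exact sample equality), exactly one zero-distance
copy is excluded — the standard leave-self-out convention.
Neighborhoods include every point within the k-th distance, so ties can
make |N_k| > k.  The reachability distance supports two variants:

* `breunig` (default): reach(C, D) = max(k-distance(D), d(C, D)) — the
  original LOF formulation, using the *neighbor's* k-distance;
* `as_printed`: reach(C, D) = max(k-distance(C), d(C, D)) — a common
  re-statement using the query's own k-distance, under which every
  in-neighborhood reachability collapses to that single value.

Both are exposed because the two appear interchangeably in the applied
literature; the default follows the original formulation.  Duplicate
clusters give zero reachability sums; their density is treated as +∞ and
the LOF of such points is defined as 1.

**Kernel.** k(A, B) = exp(−γ·d(A, B)) by default (`form="distance"`, a
Matérn-1/2-type kernel, positive definite on a Euclidean metric);
`form="squared_distance"` gives the conventional Gaussian RBF.  γ ≥ 0;
k(A, A) = 1 always.

## SVM detectors

The ν-one-class and C-soft-margin duals are delegated to libsvm via
scikit-learn with `kernel="precomputed"`: every Gram entry is produced by
the package's own distance/kernel code.  One-class dual coefficients are
rescaled to the standard ν-formulation (non-negative, each ≤ 1/(νN),
summing to 1).  Scores share one orientation — larger = more fall-like:
NN distance, LOF score, minus the one-class decision value, plus the
two-class FALL-side decision value — so ROC code is model-agnostic.
Training is deterministic given input order; the solver tolerance is
1e-6, and the ν-property (training outlier fraction ≤ ν + 1/N) is
evaluated counting decisions below −1e-6, since margin support vectors
sit at zero up to that tolerance.

## Evaluation protocol

ROC curves sweep all distinct score thresholds; AUC is the trapezoid
area, identical to the Mann–Whitney statistic P(fall > adl) + ½P(tie).
The operating point maximizes √(SE·SP); ties within 1e-12 are broken
toward higher SE (then higher SP).  The false-alarm factor is
(1 − SP_generic)/(1 − SP_personalized), undefined at SP = 1.

Pooled comparison: stratified 10-fold CV over all subjects.  Per fold,
parametric detectors choose parameters by grid search before training:
mean AUC over 10 inner 90/10 stratified holdouts of the training set,
argmax with first-in-grid-order tie-break; NN has no free parameters.
Inner holdouts sample each class proportionally but force at least one
record of each class into the held-out slice, so AUC is always defined
even on small training sets.  Novelty detectors always fit on the ADL
portion of whatever set they are handed; falls in a training set are used
only to score the inner holdouts (and by the supervised SVM).

Personalization: per subject, 10 runs each hold out a stratified 10% of
the subject's records.  Personalized training = the remaining 90% of the
subject's ADL (for the SVM also the subject's own falls by default;
`personal_falls="generic"` substitutes other-subject falls).  Generic
training = a uniform, seeded, without-replacement sample of other
subjects' ADL of equal count (and equal-count other-subject falls).  Both
conditions run their own grid search and are scored on the identical
validation slice.  Default grids: γ ∈ {2⁻⁸, 2⁻⁶, …, 2²}/m (m = median
pairwise ADL distance; m² for the squared kernel form), C ∈ {2⁻², 2⁰, …,
2⁸}, ν ∈ {0.01, 0.05, 0.1, 0.2, 0.3}, k ∈ {3, 5, 10, 20, 35} (filtered
to the exemplar count) — standard log grids scaled to the data geometry.

Paired comparisons use a two-sided Wilcoxon signed-rank test: zero
differences discarded (all-zero → p = 1); exact null by dynamic
programming over sign assignments with tie-averaged ranks for n ≤ 25;
normal approximation with continuity and tie corrections above.
Per-subject tests pair per-fold AUCs; across-subject statements pair
per-subject means; both aggregations of mean differences (over subjects
and over pooled folds) are emitted, since either convention appears in
published tables.  Significance is flagged at p < 0.05.  Win counts use
strict inequalities; exact ties (which arise when aggregating tables
printed at 4 decimals) count for neither side.

## Synthetic cohorts

Each subject has a movement signature: a pocket rotation with uniform
random axis and angle uniform on [0, `subject_divergence`] radians
(default 1.0 — pockets differ substantially between people); gait
frequency U(1.6, 2.4) Hz and amplitude U(0.10, 0.25) g; ADL burst peaks
1.5 g + LogNormal (median U(0.08, 0.25) g, σ = 0.4), so every burst
passes the 1.5 g gate; fall impacts 2 g + LogNormal (median U(0.3, 0.8)
g, σ = 0.5), i.e. essentially always saturating the sensor; measurement
noise σ ∈ U(0.01, 0.04) g.

ADL traces are gravity + gait + one qualifying burst placed ≥ 3 s from
either end.  A fraction of bursts (rate U(0.25, 0.45) per subject) are
posture-change events — sitting down hard, dropping onto a couch — with a
brief dip to 0.55–0.85 g, an impact-like burst toward the subject's
habitual resting-tilt axis (occasionally a random one), and a tilted
(0.45–1.5 rad) resting orientation afterwards.  These are deliberately
fall-like: without them, falls are trivially separable and every AUC
saturates at 1.  Fall traces are pre-fall gait, a free-fall dip (floor
0.05–0.40 g, 0.2–0.5 s; larger floors mimic compensated falls), an impact
spike along one of eight body-frame templates (forward, backward, two
lateral, syncope, sitting on empty air, compensated, obstacle), and
post-impact lying along the jittered template axis.  Sensor saturation is
applied to the magnitude at full scale (at impact one axis dominates a
real device, so full-scale clipping effectively caps the magnitude);
per-component clipping then never binds.

Everything flows through the trace → extraction path, so generated
records obey exactly the invariants real extractions would.  The default
cohort is desk-scale: 10 subjects × (100 ADL + 24 falls), 1/8 of a field
study with ~800 ADL and ~50 falls per subject, and generates in under a
second.  The acceptance experiments use this default for the pooled-CV
check and a reduced cohort (6 subjects × 40 ADL + 16 falls) for the
multi-seed benefit and divergence-monotonicity checks.

What the generator emulates — and does not.  It reproduces the structural
statistics the protocol depends on: gated peaks, window invariants,
saturation, subject-specific orientation/gait/posture styles, and the
overlap between vigorous ADL and falls that makes detection imperfect and
personalization valuable.  It is not biomechanically faithful: fall
dynamics are stylized envelopes, gait is sinusoidal, and real phone data
contains non-stationarities (pocket re-orientation within a day, surface
and footwear effects, device heterogeneity) that are absent.  Passing
tests therefore demonstrate correctness of the pipeline and the
*mechanism* of personalization (divergent subject signatures), not
field-level performance numbers.

## Numerical conventions and degenerate inputs

0-based indexing, center index 25; all accelerations in g; seeds
propagate through `numpy.random.SeedSequence` spawning (one stream per
subject; per-run substreams in the personalization loop) and stay below
2³¹.  Identical seeds give bit-identical record CSVs.  Degenerate cases
are defined rather than rejected where a convention exists (duplicate
LOF clusters → 1; all-tied scores → AUC 0.5; all-zero Wilcoxon
differences → p 1) and rejected with specific errors otherwise
(non-uniform traces, out-of-bounds windows, single-class SVM input,
empty exemplar sets, SP = 1 in the false-alarm factor).

## Known limitations

LOF is O(N²) in the exemplar count (dense distance matrix); fine at
cohort scale, not for ~10⁵ exemplars.  The one-class margin makes the
ν-property a bound only up to solver tolerance.  The published-table
aggregations inherit the 4-decimal precision of their source, which
leaves a handful of win-count cells tied.  The generator's falls always
saturate the emulated ±2 g sensor, as in the low-end devices it mimics;
higher-range sensors would need different impact priors.
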