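# fallkit

Personalizable smartphone fall detection from pocket-worn accelerometer
data: novelty detectors that learn a person's normal movements from
activities of daily living (ADL) alone, a supervised SVM baseline, and the
evaluation protocol that quantifies how much training on a user's *own*
data improves detection over a generic, other-people model.

It is aimed at researchers in wearable-sensor digital health who want to
study personalization effects without access to the original
human-subjects recordings: a synthetic multi-subject cohort generator
reproduces the structural features of real pocket-phone monitoring (50 Hz
triaxial traces in g, magnitude peaks gated at 1.5 g, eight stylized fall
types, ±2 g sensor saturation, subject-specific pocket orientation and
gait), so the whole pipeline runs end to end from a single seed.

## The model

The unit of analysis is a **record**: a 3-axis × 51-sample window (1 s at
50 Hz) of acceleration centered on a signal-magnitude peak ≥ 1.5 g.
Records A = {aᵢ} and B = {bᵢ} are compared with the distance

    d(A, B) = sqrt( Σᵢ ‖aᵢ − bᵢ‖² )

— the Euclidean distance in the 153-dimensional concatenated space.  Four
detectors produce an anomaly score (larger = more fall-like):

* **NN** — distance to the nearest ADL exemplar, d_NN(C) = minⱼ d(C, Bʲ);
  parameter-free.
* **LOF(k)** — local outlier factor: the ratio of the mean local
  reachability density of C's k-neighborhood to C's own; ≈ 1 inside
  clusters, > 1 for outliers.
* **One-class SVM(ν, γ)** — maximum-margin support estimation over the
  record kernel k(A, B) = exp(−γ d(A, B)); ν upper-bounds the training
  outlier fraction.
* **SVM(C, γ)** — soft-margin two-class baseline trained on ADL + falls
  with the same kernel.

Detectors are compared by the area under the ROC curve (AUC); sensitivity
and specificity are read at the ROC point maximizing √(SE·SP).  The
**personalization protocol** compares, per subject and over 10 stratified
90/10 runs, a detector trained on the subject's own ADL against one
trained on an equal number of other subjects' ADL, both scored on the
identical held-out slice; paired results are tested with a two-sided
Wilcoxon signed-rank test.

## Worked example

`examples/04_personalization.py` generates a six-subject cohort and runs
the personalized-vs-generic comparison for the NN detector:

```
 subject   PNN AUC   GNN AUC     diff        p
     S01    0.9917    0.7500  +0.2417   0.0078
     S02    0.9917    1.0000  -0.0083   1.0000
     S03    1.0000    0.9667  +0.0333   0.2500
     S04    1.0000    0.9917  +0.0083   1.0000
     S05    1.0000    0.6000  +0.4000   0.0156
     S06    0.9917    1.0000  -0.0083   1.0000

mean AUC improvement from personalization: +0.1111
mean SP personalized 0.9917 vs generic 0.8972 -> false alarms reduced by a factor of 12.33
```

PNN/GNN are the personalized/generic nearest-neighbor detectors.  The
benefit is strongly subject-dependent — large for subjects whose pocket
orientation and movement style deviate from the rest (S01, S05), absent
for subjects already well covered by other people's data — which is the
qualitative signature of personalization.  The false-alarm factor
(1 − SP_generic)/(1 − SP_personalized) converts the specificity gain into
"how many times fewer false alarms per day".

The other examples cover record extraction (`01`), novelty scoring (`02`),
the pooled four-detector comparison (`03`), and aggregation of the
published per-subject study tables (`05`).

A thin CLI wraps the same library paths:

```
fallkit simulate --out sim --seed 1
fallkit evaluate --records sim/records.csv --mode personalization \
        --algorithms nn --out results
fallkit report results/results.csv
```

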