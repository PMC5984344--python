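# Methods

This note documents the models, protocols and numerical choices behind
`crrnet`, and what its synthetic benchmarks do and do not demonstrate.

## Coordinates and feature extraction

All coordinates are 0-based half-open (BED convention).  A region's feature
value for a track is the length-weighted mean signal over the window
`[mid − w/2, mid + w/2)` with `mid = floor((start+end)/2)` and `w` the bin
width (default 200 bp; 200/500/1000/2000/4000 are the supported choices and
200 is the default because it performs best in cross-validation for
regulatory-region classification).  Two conventions matter and are fixed
here:

* bases not covered by any track segment contribute **zero** signal, and the
  mean is taken over the full window, not only covered bases;
* windows extending past a chromosome edge are truncated and averaged over
  the covered part — no signal is fabricated beyond the assembly.

Strand is ignored for feature extraction.  A chromosome present in the
genome table but absent from a track yields 0 with a logged warning (a
track's coverage can legitimately omit a chromosome); a chromosome missing
from the genome table is an error.

## Labeling rules

Enhancers: TPM > 0 → A-E, TPM = 0 → I-E.  Promoters: TPM > 5 → A-P,
TPM = 0 → I-P.  Exons: peak-max > 400 → A-X, peak-max = 0 → I-X.  Regions
between the two tails (promoters with 0 < TPM ≤ 5, exons with
0 < peak-max ≤ 400) are deliberately left unlabelled rather than forced into
either class: the definitions describe only the confident extremes, and
ambiguous mid-range regions would dilute both.

UK (unknown) regions are drawn by uniform rejection sampling of fixed-width
windows outside an exclusion mask (transcribed tags, exons, open chromatin),
mutually disjoint.  Width and count are configuration parameters; the
feasibility check (sum of floor(gap/width) over unmasked gaps) reports the
achievable maximum when a request cannot be met.

## Training protocol

The classifier is a feedforward softmax network with ReLU hidden layers
(at most three; the default search grid caps sizes at 256/128/64).  Loss is
mean cross-entropy plus (ℓ2/2)·Σ‖W‖²; optimization is mini-batch SGD with
momentum, batch size 100, and at most 1000 iterations, where an *iteration*
is one pass over the shuffled mini-batches.  The learning rate follows
`rate_i = rate_0 / (1 + δ·i)` with δ = 0 by default (no decay).  Validation
loss is evaluated every 5 iterations; training stops after 10 evaluations
without improvement and the best-validation snapshot is returned, so the
returned network's validation loss never exceeds the final iterate's.
Weights are initialized symmetric-uniform with limit √(6/(fan_in+fan_out));
all randomness (initialization, batch order) flows from one seeded
generator, so training is exactly reproducible.

Per evaluation run: a balanced training set is drawn (per class
min(⌊0.7·n⌋, 3000)); min–max scaling factors are estimated on it and applied
unchanged to validation and test data (test values may fall outside [0,1];
constant features map to 0); the training set is split 75/25 into fit and
validation subsets, stratified by class; model search trains every candidate
and keeps the best validation class-wise rate, breaking ties toward fewer
parameters; the test set is drawn from the remainder with class composition
exactly u·(1:1:1:2:2:1:10) for the largest feasible integer u (anchoring at
the most limiting class keeps the ratio exact at the cost of discarding
surplus examples).  The whole procedure repeats n times with consecutive
seeds and reports means and standard deviations.

When a corpus already carries coarse task labels, the background ratio is
aggregated through the class scheme: BG = I-E+I-P+A-X+I-X+UK gives
A-E : A-P : BG = 1 : 1 : 16 and CRR : BG = 2 : 16.

## Metrics

* **CWR** — unweighted mean of per-class sensitivities; for two classes this
  equals the mean of sensitivity and specificity.
* **auROC** — probability a random positive outscores a random negative,
  ties counted ½ (computed from average ranks).
* **auPRC** — precision accumulated at each recall step in descending-score
  order with index tie-break, no interpolation (average precision).  These
  tie conventions are part of the contract because reported numbers depend
  on them.
* Multi-class tasks use macro one-vs-rest reductions of both areas.

## Deep feature selection

The selection layer multiplies each input by its own weight (w·x element-
wise) before the network body.  The penalty λ‖w‖₁ is handled by proximal
(soft-threshold) updates after the momentum step on the smooth loss, which
produces exact zeros — this matters because the package's no-influence
guarantee ("a feature with wᵢ = 0 cannot affect any output, no matter how it
is perturbed") is exact, not approximate, and because selection counts below
depend on true zeros.  An elastic-net mixing parameter is available
(`l1_mix` < 1 adds an ℓ2 term on w); the default is pure ℓ1.  With λ = 0 the
proximal step is the identity, so a frozen-w DFS network reproduces the
plain network bit for bit under a shared seed.

**Randomized DFS.**  Each of R runs draws a class-stratified subsample
(default half) of the training set, multiplies λ per feature by an
independent Uniform[α, 1] draw (α = 0.5), trains DFS, and records the top-K
features by |w| (K = 10 by default, descending magnitude, index tie-break).
A feature whose weight is exactly zero is never counted as selected, so a
strongly-shrunk run may select fewer than K features; counting inert
features would make importances depend on index tie-breaks among zeros.
Importance = selection count / R.

**λ default (0.2 on [0,1]-scaled features).**  Chosen on planted synthetic
data so that the proximal step zeroes essentially all uninformative weights
while retaining planted markers across subsamples; at much smaller λ no
weight reaches zero and every run must pad its top-K with noise features,
while at much larger λ genuinely informative features start dropping out.
λ is the one hyperparameter users should re-examine on real data, e.g. by
inspecting the nonzero-weight count along a λ path.

**Stability caveat.**  Rank correlation of importance vectors between
independent seed sets is dominated by ties at zero: a single stray noise
selection (frequency 1/R) can sharply drop Spearman's ρ even when the
ranking of real features is identical.  The stability test therefore runs in
a regime (λ = 0.3, R = 25) where noise selections are rare, and additionally
checks that the planted features occupy the top ranks in both seed sets.

## Feature-count selection

`fit_arctan` minimizes squared residuals of y = (2s/π)·arctan(kx) with
k, s > 0, initialized at k₀ = 1, s₀ = max y, iterating until the step falls
below 1e−10 (at most 500 evaluations).  The tangent point for slope t
(default 0.5) is closed-form; the operating feature count is m = ⌈x_t⌉
since subset sizes are integers.  t must lie strictly below the slope at
the origin, 2ks/π, or no tangent point exists.  An all-zero curve fits a
degenerate s → 0 and warns.

## Genome-wide annotation

The genome is tiled into non-overlapping bins (trailing partial bins are
dropped; a sliding step is intentionally not the default).  Bins are
classified streaming one chromosome at a time, labels are argmax membership
(lowest index on ties), and maximal runs of touching same-class bins merge
into one region whose score is the mean (optionally max) of bin scores.
Background regions are omitted from BED output by default; the summary JSON
retains their counts and genome fractions.  Merging is idempotent.

## Synthetic benchmarks — what they show and what they don't

`simulate_feature_data` plants class-marker features: each informative
feature's latent (log-scale) location is shifted by `effect_size` pooled
SDs for one class, then exponentiated, giving non-negative right-skewed
signals like coverage data; noise features are iid across classes.  Default
study conditions are 600 examples per class, 20 informative + 30 noise
features, effect size 2.  `simulate_genome_fixture` plants bin-aligned
enhancer/promoter/exon loci on a 2 × 100 kb toy genome with five tracks whose
elevation profiles mimic regulatory marks (an enhancer-specific mark, a
promoter-specific mark, shared activity/accessibility marks, transcription
at active exons), with TPM/peak-max metrics drawn consistent with the
labeling thresholds.

These fixtures validate the machinery — protocol arithmetic, optimization,
selection frequencies, annotation plumbing — under conditions where the
right answer is known.  They do **not** emulate the hard parts of real
epigenomic data: correlated assays, heavy-tailed and batch-affected
coverage, diffuse or asymmetric signal around regulatory elements, ambiguous
labels near thresholds, or class imbalance beyond the prescribed background
ratio.  Passing benchmarks therefore demonstrates correctness of the
implementation, not expected performance on a real genome.

## Problem sizes

The test-suite and acceptance-script runs use deliberately compact problem
sizes chosen as the smallest that still exercise each property cleanly:
networks of at most one 16–32-unit hidden layer, 60–150 training iterations,
10 protocol repeats, R = 25–30 randomized-DFS runs, and the 200 kb toy
genome (1000 bins).  All are configuration parameters, and the defaults for
real use (e.g. `max_iter = 1000`) follow the protocol above.

## Known limitations

* No convolutional/recurrent variants, no dropout, no GPU path.
* bigWig input is not wired in; tracks are text bedGraph (the `SignalTrack`
  contract would accept an adapter).
* The λ default is calibrated on synthetic data; real feature sets with
  different scales or correlation structure may need a different value.
* UK sampling is uniform; it does not model mappability or blacklist
  structure.
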