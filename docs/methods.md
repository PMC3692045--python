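# Methods

This note documents the models and procedures implemented in `kmersvm`,
the parameters that matter, the numerical choices made where the design was
open, and what the synthetic benchmark does and does not establish.

## Feature map and kernel

A sequence `s` is mapped to a count vector over *canonical* kmers. For each
window of length k (case-folded; windows containing N are skipped, never
imputed), the window and its reverse complement are collapsed to their
lexicographic minimum and that single feature is incremented once — so a
palindromic kmer is one feature counted once, avoiding the double-counting
bias that would arise from keeping both strands as separate features. For
kmer length k there are (4^k + p(k))/2 canonical features, with
p(k) = 4^(k/2) palindromes for even k and p(k) = 0 for odd k (an odd-length
DNA string cannot be its own reverse complement); k = 6 gives 2080 features.

The count vector is L2-normalised, making the spectrum kernel
k(x, y) = ⟨φ(x), φ(y)⟩ with k(x, x) = 1 and k(x, y) ∈ [0, 1]. For the
weighted spectrum variant over a range k_min..k_max, each k-block is
independently L2-normalised and the blocks concatenated with coefficient
1/√(#k) ("equal weighting"), keeping the composite vector unit-norm. The
normalise-per-k-then-concatenate order is a documented choice; normalising
after concatenation would weight larger k-blocks by their raw counts.

Feature vectors are exactly strand-invariant: φ(s) = φ(revcomp(s))
coordinatewise, which propagates to identical SVM and PWM scores for a
sequence and its reverse complement.

## SVM training

The spectrum kernel is the inner product of an explicit, modest-dimensional
feature map, so the model is trained directly in that space with a linear
soft-margin SVM (libsvm's SMO via scikit-learn's `SVC(kernel="linear")`).
This is mathematically identical to the kernelised dual problem, and the
primal coefficient vector is precisely the per-kmer weight table that makes
the model interpretable; the identity between weight-table scores and the
support-vector kernel expansion is property-tested to 1e-6.

Parameters:

* **k** (default 6): kmer length. Single k is the most interpretable;
  a range (weighted spectrum) trades vocabulary simplicity for a small
  accuracy gain.
* **C** (default 1.0): misclassification cost for negatives. Small C
  underfits slightly; large C overfits.
* **PSW** (default `"auto"` = 1 + ln(N/P), floored at 1): multiplier on the
  positive-class cost, so positives cost C·PSW and negatives C. The
  logarithmic form grows slowly with imbalance; the floor prevents
  down-weighting positives when they outnumber negatives. Natural log is
  used (the base was an open choice; ln makes N = e²·P give PSW = 3
  exactly). Raising PSW never decreases training-set sensitivity
  (property-tested).
* **E** (default 1e-5): solver termination tolerance. Looser E yields fewer
  support vectors and faster training; results are insensitive over
  1e-5..1e-3 (tested as |ΔAUROC| < 0.01).
* **n_folds** (default 5), **seed**: cross-validation is stratified (class
  proportions preserved per fold — with 10× negatives an unstratified fold
  can starve a test fold of positives) and seeded; the solver itself is
  deterministic, so identical inputs and config reproduce identical models,
  folds and predictions.

The published weight table comes from a final model trained on *all* data;
performance estimates and calibration use only the pooled held-out CV
scores. Ranked outputs break weight ties lexicographically on the kmer so
tables are deterministic.

## Null-set generation

For each requested negative (fold_increase × |positives| in total,
positives visited in a seeded random cycle), the sampler draws uniform
starts on the source positive's chromosome and accepts the first window of
exactly the positive's length whose GC and repeat fractions lie within the
absolute tolerances (default ±0.02 each), whose N fraction is ≤ 0.1
(assembly gaps are unusable), and which overlaps no positive, excluded, or
previously accepted interval by even one base pair. Window statistics come
from per-chromosome prefix-sum tables of GC/masked/N counts (O(1) per
candidate, exact integer arithmetic — property-tested equal to direct
recounting).

Tolerances are absolute (percentage points), not relative; matching is
strictly same-chromosome. Repeat fraction is defined as the soft-masked
(lowercase) fraction, the standard way RepeatMasker annotation travels in
genome FASTA.

If rejection sampling exhausts its budget (`max_attempts`, default 10,000)
for a positive, the sampler falls back to an exhaustive chunked scan of
every start on the chromosome and picks uniformly at random among the
in-tolerance, non-overlapping windows — so any matchable positive is
matched *within* tolerance regardless of how rare such windows are. Only
when no in-tolerance window exists at all are both tolerances doubled once
(such negatives are flagged `relaxed` in the report); a positive that still
cannot be matched is skipped with a warning. Blocked intervals are stored
merged-disjoint per chromosome so overlap checks stay exact even when input
positives overlap each other.

## Performance evaluation

ROC and PR curves are computed from pooled CV scores (not per-fold
averages) with scikit-learn's curve machinery; tied scores collapse to a
single threshold step, which makes the trapezoidal AUROC agree exactly with
the Mann–Whitney pairwise-concordance statistic (ties counted ½) — the
probabilistic reading "AUROC = P(random positive outscores random
negative)". AUPRC is reported as non-interpolated average precision
(precision summed over recall increments), not the PR trapezoid, because
trapezoidal interpolation between PR points is optimistic. Under growing
negative imbalance at fixed score quality AUROC is stable while AUPRC
falls, which is why PR is the more informative view for 10× negative sets
(property-tested).

## Posterior calibration

Platt scaling fits P(+|s) = 1/(1 + exp(A·s + B)) by regularised maximum
likelihood on the pooled held-out CV scores — never on resubstitution
scores, which would bias the sigmoid optimistic. The implementation follows
the numerically stable formulation: Bayesian-prior targets (P+1)/(P+2) and
1/(N+2) instead of hard 1/0 labels, the two-branch stable form of the
cross-entropy, and a damped Newton iteration with backtracking line search.
A < 0 whenever higher scores favour the positive class, making the
posterior strictly increasing in the score.

## Genome tiling

`split_genome(c, v)` tiles each chromosome with windows of length c
starting at multiples of c − v, so consecutive windows overlap by exactly
v bp. A trailing shorter window is emitted only when at least c/2 bp would
otherwise remain uncovered — a documented boundary rule that avoids
near-empty windows at chromosome ends. Sequences shorter than the smallest
k score at the model bias with a warning flag rather than failing, so
genome-wide scans stay total.

## Motif tools

* **Kmer → PWM**: consensus-delta construction — probability 1 − 3α on the
  kmer's base per column, α elsewhere (default α = 0.01; α keeps log-odds
  finite). One PWM per kmer; at most 50 kmers per MEME export, enforced.
  MEME minimal format round-trips byte-identically.
* **Log-odds scanning**: max over positions and both strands of
  Σ log2(p/q) against a background q (uniform by default), in bits. N
  positions contribute 0 bits. A sequence shorter than the motif scores
  −inf (flagged minimal) so it never outranks a scannable one.
* **Similarity**: all ungapped offsets with ≥ min_overlap (default 4)
  aligned columns, both target orientations; similarity is the mean
  per-column score — Pearson correlation of the 4-vectors, negated
  Euclidean distance, or the Sandelin–Wasserman column score 2 − Σ(p−q)².
  Pearson on a zero-variance (uniform) column is undefined; it is taken as
  1.0 iff both aligned columns are equal, else 0.0. Matches rank by raw
  similarity with deterministic name tie-breaks; no E-/q-value null
  statistics are computed.

## Synthetic benchmark

The generator emulates TF-peak training data: i.i.d. background at a
specified GC fraction (default 0.42, a typical mammalian genome-wide
value), 100-bp elements (short TF peaks extended from their midpoints),
one occurrence of each planted consensus per sequence at a uniform random
position and random strand, and toy genomes with contiguous 500-bp
soft-masked stretches (approximating the clustered layout of repeat
annotation). The default benchmark plants AAGGTC in 90% of 1000 positives
with a 10× negative set; the benchmark used for end-to-end checks adds a
repressor-like kmer (GCGATC, planted in 80% of negatives only) so that
large *negative* weights — absence predicting positivity — are exercised
as well. The two-motif variant (two consensus kmers each at 0.6, positives
required to carry at least one) models a combinatorial vocabulary and is
the setting where the SVM demonstrably beats the best single-PWM
max-log-odds baseline.

What the generator does **not** emulate: dinucleotide or higher-order
background structure, motif degeneracy (planted sites are exact consensus
copies), variable element lengths, chromatin context, and peak-calling
noise. Passing tests therefore establish the correctness of the machinery
and its behaviour under controlled signal, not expected accuracy on real
ChIP-seq data, where weaker and degenerate signals yield lower absolute
performance.

Problem sizes used by the test suite and the acceptance script (1000
positives × 100 bp with 10× negatives for the benchmark; 500 positives
with 5× negatives for the two-motif comparison; 2-Mb toy genomes for null
sampling) were chosen as the smallest scales at which the benchmark's
statistical claims are stable across seeds.

## Known limitations

* Genomes are held in memory as plain strings; fine through mammalian
  scale on a workstation, but there is no streaming/indexed-file path.
* Exact-match spectrum kernels only — no mismatch, gapped, or
  position-specific kernels; long degenerate binding sites (e.g.
  CTCF-like) are not handled optimally by short exact kmers.
* Tomtom-style match significance (E-/q-values) is out of scope; rankings
  are by raw similarity.
* libsvm training is O(n²)-ish in the sample count; tens of thousands of
  sequences are practical, hundreds of thousands are not.
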