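# kmersvm

Learning predictive regulatory sequence vocabularies from genomic region
sets with a spectrum-kernel support vector machine.

## The problem

ChIP-seq and DNase-seq experiments yield thousands of genomic regions bound
by a transcription factor or marked as open chromatin. The hard part is the
sequence code underneath: which short DNA words (kmers), in combination,
distinguish these regions from the rest of the genome? Single-motif scanning
(one PWM, best hit per region) often underperforms because regulatory
activity is combinatorial — clusters of binding sites for several factors,
plus sites whose *absence* matters (repressors).

`kmersvm` addresses this for computational biologists analysing their own
peak sets:

1. **Profile-matched null sets.** Negatives are sampled from the same
   chromosomes with exactly matched length and GC/repeat fractions within a
   tolerance (default ±0.02), overlapping no positive, excluded, or
   previously accepted interval by even one base pair. Without this matching
   a classifier partly learns composition bias instead of binding sites.
2. **Strand-collapsed spectrum-kernel SVM.** Each sequence maps to an
   L2-normalised count vector over canonical kmers — each {kmer, reverse
   complement} pair collapsed to one feature, since factors bind
   double-stranded DNA. The spectrum kernel is the inner product of these
   vectors, so a linear SVM in the explicit feature space is exactly the
   kernelised model, and its coefficient vector *is* an interpretable
   per-kmer weight table. Class imbalance is handled by a positive-set
   weight, default PSW = 1 + ln(N/P).
3. **Honest evaluation and calibrated scoring.** Stratified n-fold CV pools
   held-out scores for ROC/PR curves (AUROC = probability a random positive
   outscores a random negative; AUPRC = average precision, the right metric
   under 10× negative imbalance), and a Platt sigmoid
   P(+|s) = 1/(1 + exp(A·s + B)) fitted on those held-out scores turns SVM
   scores of arbitrary sequences — or genome-wide tiles from `split_genome`
   — into posterior probabilities.
4. **Motif tools.** Top/bottom-weighted kmers export as MEME-format PWMs
   (≤50 per file); sequences can be scored by max log2-odds of a PWM over
   both strands; and PWMs can be compared column-wise (Pearson, Euclidean,
   Sandelin–Wasserman) against a motif database.

A seeded synthetic generator (toy genomes, planted-motif positive/negative
sets with ground truth) makes the entire pipeline testable without any
downloads.

## Worked example

```python
import kmersvm as kv
from kmersvm.svmcore import calibrate

config = kv.SyntheticConfig(
    n_pos=400, seq_length=100, gc_background=0.42, fold_negatives=5, seed=11,
    motifs=(kv.MotifSpec("AAGGTC", 0.9),
            kv.MotifSpec("GCGATC", 0.8, role="negative_only")),
)
sets = kv.generate_labeled_sets(config)
space = kv.build_feature_space(6)                  # 2080 canonical 6-mers
Xp = kv.featurize_matrix(sets.positives, space)
Xn = kv.featurize_matrix(sets.negatives, space)

train_cfg = kv.TrainConfig(k=6, C=1.0, E=1e-5, psw="auto", n_folds=5, seed=11)
preds = kv.cross_validate(Xp, Xn, train_cfg, space=space)
model = calibrate(kv.train(Xp, Xn, train_cfg, space=space), preds)
print(kv.evaluate_predictions(preds))
print(kv.extract_weights(model).head(5))
```

This prints (see `examples/02_train_and_interpret.py` for the full script):

```
PSW = 2.6094 (auto: 1 + ln(2000/400))
pooled CV AUROC = 0.9786, AUPRC = 0.9102

top 5 kmers (presence predicts positive):
  kmer revcomp    weight
AAGGTC  GACCTT 10.990750
AGACCT  AGGTCT  2.509074
ACCTTA  TAAGGT  2.378774
AAAGGT  ACCTTT  2.317798
AGGTCC  GGACCT  2.221180

bottom 3 kmers (absence predicts positive):
  kmer revcomp    weight
CGATCA  TGATCG -1.615377
AGCGAT  ATCGCT -1.642146
GATCGC  GCGATC -5.634832
```

The planted kmer AAGGTC tops the table (large positive weight: its presence
predicts the positive class); the next-ranked kmers overlap it — the SVM
vocabulary spans the binding site. The repressor-like kmer GCGATC, present
only in negatives, receives the most negative weight: its absence predicts
positivity. The CV AUROC of 0.979 means a random positive outscores a random
negative 97.9% of the time on held-out data.

More narrative scripts live in `examples/`: profile-matched null generation
(`01`), training and interpretation (`02`), and PWM export/comparison plus
the SVM-vs-single-PWM baseline (`03`).

## Command line

Every step is also a subcommand of the `kmersvm` console script, operating
on BED/FASTA/TSV/MEME files: `profile`, `nullseq`, `featurize`, `train`,
`evaluate`, `score`, `splitgenome`, `kmer2meme`, `pwmscan`, `motifmatch`,
`synth`. Run `kmersvm COMMAND --help` for options.

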