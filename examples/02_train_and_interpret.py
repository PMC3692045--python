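"""Train a kmer-SVM on planted-motif data and read its weight vocabulary.

Positives are 100-bp background sequences carrying the consensus AAGGTC in
90% of cases; a repressor-like kmer GCGATC appears only in the negatives.
After 5-fold CV the pooled held-out scores give the performance estimate,
and the full-data model's per-kmer weights expose the learned vocabulary:
the planted kmer should top the table and the repressor kmer should receive
a strongly negative weight.
"""

import numpy as np

import kmersvm as kv
from kmersvm.svmcore import calibrate

config = kv.SyntheticConfig(
    n_pos=400, seq_length=100, gc_background=0.42, fold_negatives=5, seed=11,
    motifs=(
        kv.MotifSpec("AAGGTC", 0.9),
        kv.MotifSpec("GCGATC", 0.8, role="negative_only"),
    ),
)
sets = kv.generate_labeled_sets(config)

space = kv.build_feature_space(6)          # 2080 strand-collapsed 6-mers
Xp = kv.featurize_matrix(sets.positives, space)
Xn = kv.featurize_matrix(sets.negatives, space)

train_cfg = kv.TrainConfig(k=6, C=1.0, E=1e-5, psw="auto", n_folds=5, seed=11)
preds = kv.cross_validate(Xp, Xn, train_cfg, space=space)
perf = kv.evaluate_predictions(preds)
model = calibrate(kv.train(Xp, Xn, train_cfg, space=space), preds)

print(f"PSW = {model.psw:.4f} (auto: 1 + ln({model.n_neg}/{model.n_pos}))")
print(f"pooled CV AUROC = {perf['auroc']:.4f}, AUPRC = {perf['auprc']:.4f}")

table = kv.extract_weights(model)
print("\ntop 5 kmers (presence predicts positive):")
print(table.head(5).to_string(index=False))
print("\nbottom 3 kmers (absence predicts positive):")
print(table.tail(3).to_string(index=False))

# score novel sequences: raw SVM score plus calibrated posterior
queries = ["TTTTTTTTTTAAGGTCTTTTTTTTTT", "TTTTTTTTTTGCGATCTTTTTTTTTT"]
scored = kv.score_sequences(queries, model)
print("\nscoring novel sequences (posterior = P(positive | score)):")
print(scored[["seq_id", "svm_score", "posterior"]].to_string(index=False))
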