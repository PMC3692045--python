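"""SVM training, cross-validation, weight tables, calibration, scoring."""

import math

import numpy as np
import pytest

import kmersvm as kv
from kmersvm.svmcore import calibrate

from conftest import random_sequences


def _separable_sets(space, n=40, length=60, seed=31, motif="AAGGTC"):
    """Positives all contain the motif; negatives are motif-free background."""
    rng = np.random.default_rng(seed)
    pos, neg = [], []
    rc = kv.reverse_complement(motif)
    while len(pos) < n or len(neg) < n:
        s = random_sequences(rng, 1, length)[0]
        has = motif in s or rc in s
        if not has and len(neg) < n:
            neg.append(s)
        elif len(pos) < n:
            if not has:
                i = int(rng.integers(0, length - len(motif) + 1))
                s = s[:i] + motif + s[i + len(motif):]
            pos.append(s)
    return kv.featurize_matrix(pos, space), kv.featurize_matrix(neg, space)


class TestAutoPsw:
    @pytest.mark.parametrize(
        "P,N,expected",
        [
            (100, 100, 1.0),
            (10, 100, 1.0 + math.log(10)),
            (1000, 100, 1.0),  # floored when negatives are the minority
        ],
    )
    def test_formula(self, P, N, expected):
        assert kv.auto_psw(P, N) == pytest.approx(expected, abs=1e-12)

    def test_e_squared_ratio_gives_three(self):
        assert kv.auto_psw(100, 100 * math.e**2) == pytest.approx(3.0, abs=1e-12)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            kv.auto_psw(0, 10)


class TestTrain:
    def test_separable_toy_set(self, space6):
        Xp, Xn = _separable_sets(space6)
        model = kv.train(Xp, Xn, kv.TrainConfig(), space=space6)
        scores = model.decision_function(np.vstack([Xp, Xn]))
        labels = np.r_[np.ones(len(Xp)), -np.ones(len(Xn))]
        assert (np.sign(scores) == labels).all()  # 100% training accuracy
        table = kv.extract_weights(model)
        assert table.iloc[0]["kmer"] == "AAGGTC"

    def test_primal_dual_score_identity(self, space6):
        rng = np.random.default_rng(37)
        Xp, Xn = _separable_sets(space6, n=30)
        model = kv.train(Xp, Xn, space=space6)
        held_out = kv.featurize_matrix(random_sequences(rng, 50, 60), space6)
        primal = model.decision_function(held_out)
        dual = model.decision_function_dual(held_out)
        assert np.abs(primal - dual).max() < 1e-6

    def test_weight_table_covers_space_and_reproduces_scores(self, space6):
        Xp, Xn = _separable_sets(space6, n=20)
        model = kv.train(Xp, Xn, space=space6)
        table = kv.extract_weights(model)
        assert len(table) == len(space6) == 2080
        # linearity: sum(weight * feature value) == score - bias
        w_by_kmer = dict(zip(table["kmer"], table["weight"]))
        x = Xp[3]
        recon = sum(
            w_by_kmer[space6.kmers[j]] * x[j] for j in x.nonzero()[0]
        )
        assert recon == pytest.approx(
            float(model.decision_function(x[None, :])[0]) - model.bias, abs=1e-9
        )

    def test_cost_weighting_semantics(self, space6):
        """Duplicating every negative while halving the negative cost leaves
        the primal objective value unchanged."""
        Xp, Xn = _separable_sets(space6, n=25, seed=41)

        def objective(model, Xp_, Xn_, c_pos, c_neg):
            w, b = model.weights, model.bias
            hp = np.maximum(0, 1 - (Xp_ @ w + b))
            hn = np.maximum(0, 1 + (Xn_ @ w + b))
            return 0.5 * w @ w + c_pos * hp.sum() + c_neg * hn.sum()

        m1 = kv.train(Xp, Xn, kv.TrainConfig(C=1.0, psw=2.0), space=space6)
        Xn2 = np.vstack([Xn, Xn])
        # halving C scales both classes; restore the positive cost via psw
        m2 = kv.train(Xp, Xn2, kv.TrainConfig(C=0.5, psw=4.0), space=space6)
        o1 = objective(m1, Xp, Xn, c_pos=2.0, c_neg=1.0)
        o2 = objective(m2, Xp, Xn2, c_pos=2.0, c_neg=0.5)
        assert o2 == pytest.approx(o1, rel=1e-3)

    def test_psw_monotone_in_training_sensitivity(self, space6):
        """Raising the positive-set weight never decreases the fraction of
        positives classified correctly on a fixed noisy set."""
        rng = np.random.default_rng(43)
        cfg = kv.SyntheticConfig(
            n_pos=60, fold_negatives=4, seed=47,
            motifs=(kv.MotifSpec("AAGGTC", 0.5),),
        )
        sets = kv.generate_labeled_sets(cfg)
        Xp = kv.featurize_matrix(sets.positives, space6)
        Xn = kv.featurize_matrix(sets.negatives, space6)
        sens = []
        for psw in (1.0, 3.0, 10.0):
            m = kv.train(Xp, Xn, kv.TrainConfig(psw=psw), space=space6)
            sens.append(float((m.decision_function(Xp) > 0).mean()))
        assert sens == sorted(sens)

    def test_seeded_determinism(self, space6):
        Xp, Xn = _separable_sets(space6, n=20)
        m1 = kv.train(Xp, Xn, space=space6)
        m2 = kv.train(Xp, Xn, space=space6)
        assert (m1.weights == m2.weights).all() and m1.bias == m2.bias


class TestCrossValidate:
    def _sets(self, space):
        cfg = kv.SyntheticConfig(n_pos=50, fold_negatives=2, seed=53)
        sets = kv.generate_labeled_sets(cfg)
        return (
            kv.featurize_matrix(sets.positives, space),
            kv.featurize_matrix(sets.negatives, space),
        )

    def test_stratified_partition_and_coverage(self, space6):
        Xp, Xn = self._sets(space6)
        preds = kv.cross_validate(Xp, Xn, kv.TrainConfig(n_folds=5), space=space6)
        assert len(preds) == len(Xp) + len(Xn)
        ids = [p.seq_id for p in preds]
        assert len(set(ids)) == len(ids)  # each sequence scored exactly once
        for fold in range(5):
            in_fold = [p for p in preds if p.fold == fold]
            n_pos = sum(p.true_label == 1 for p in in_fold)
            n_neg = sum(p.true_label == -1 for p in in_fold)
            assert abs(n_pos - len(Xp) / 5) <= 1
            assert abs(n_neg - len(Xn) / 5) <= 1

    def test_same_seed_identical_predictions(self, space6):
        Xp, Xn = self._sets(space6)
        cfg = kv.TrainConfig(n_folds=4, seed=7)
        a = kv.cross_validate(Xp, Xn, cfg, space=space6)
        b = kv.cross_validate(Xp, Xn, cfg, space=space6)
        assert [(p.seq_id, p.fold, p.svm_score) for p in a] == [
            (p.seq_id, p.fold, p.svm_score) for p in b
        ]

    def test_too_many_folds_rejected(self, space6):
        Xp, Xn = self._sets(space6)
        with pytest.raises(ValueError):
            kv.cross_validate(
                Xp[:3], Xn, kv.TrainConfig(n_folds=5), space=space6
            )

    def test_tolerance_insensitivity(self, space6):
        """Loosening the solver precision E barely moves CV AUROC."""
        Xp, Xn = self._sets(space6)
        aurocs = []
        for E in (1e-5, 1e-3):
            preds = kv.cross_validate(
                Xp, Xn, kv.TrainConfig(E=E, n_folds=3), space=space6
            )
            aurocs.append(kv.roc_curve(preds).area)
        assert abs(aurocs[0] - aurocs[1]) < 0.01


class TestPosterior:
    def test_symmetric_separable_scores(self):
        rng = np.random.default_rng(59)
        scores = np.r_[1 + 0.05 * rng.standard_normal(200),
                       -1 + 0.05 * rng.standard_normal(200)]
        labels = np.r_[np.ones(200), -np.ones(200)]
        A, B = kv.fit_posterior((scores, labels))
        assert A < 0
        p0 = 1.0 / (1.0 + math.exp(B))  # posterior at score 0
        assert 0.45 < p0 < 0.55

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(61)
        scores = rng.standard_normal(300)
        labels = np.where(scores + 0.5 * rng.standard_normal(300) > 0, 1, -1)
        A, B = kv.fit_posterior((scores, labels))
        # evaluate across the observed score range, extended by one width
        width = float(scores.max() - scores.min())
        lo, hi = scores.min() - width, scores.max() + width
        grid = np.linspace(lo, hi, 400)
        post = 1.0 / (1.0 + np.exp(A * grid + B))
        assert ((post > 0) & (post < 1)).all()
        assert (np.diff(post) > 0).all()  # A < 0 => increasing in score

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            kv.fit_posterior((np.ones(5), np.ones(5)))


class TestScoreSequences:
    def test_single_kmer_sequence_scores_weight_plus_bias(self, space6):
        Xp, Xn = _separable_sets(space6, n=20)
        model = kv.train(Xp, Xn, space=space6)
        s = kv.score_sequences(["AAGGTC"], model)
        w = model.weights[space6.index_of("AAGGTC")]
        assert s["svm_score"][0] == pytest.approx(w + model.bias, abs=1e-12)

    def test_strand_invariant_scoring(self, space6):
        Xp, Xn = _separable_sets(space6, n=15)
        model = kv.train(Xp, Xn, space=space6)
        seq = "ACAAGGTCTTGACAACGT"
        a = model.score_record(seq)
        b = model.score_record(kv.reverse_complement(seq))
        assert a == pytest.approx(b, abs=1e-12)

    def test_short_sequence_flagged_at_bias(self, space6):
        Xp, Xn = _separable_sets(space6, n=15)
        model = kv.train(Xp, Xn, space=space6)
        with pytest.warns(UserWarning, match="no countable"):
            s = kv.score_sequences(["ACG"], model)
        assert s["flagged"][0]
        assert s["svm_score"][0] == pytest.approx(model.bias)

    def test_calibrated_scores_round_trip_weights_file(self, space6, tmp_path):
        Xp, Xn = _separable_sets(space6, n=20)
        cfg = kv.TrainConfig(n_folds=3)
        preds = kv.cross_validate(Xp, Xn, cfg, space=space6)
        model = calibrate(kv.train(Xp, Xn, cfg, space=space6), preds)
        path = tmp_path / "weights.tsv"
        kv.save_weights(model, path)
        loaded = kv.load_weights(path)
        rng = np.random.default_rng(67)
        for seq in random_sequences(rng, 5, 60):
            assert loaded.score_record(seq) == pytest.approx(
                model.score_record(seq), abs=1e-8
            )
        assert loaded.posterior_A == pytest.approx(model.posterior_A)


class TestSplitGenome:
    def test_overlapping_windows_with_dropped_tail(self):
        wins = kv.split_genome({"chr1": 1000}, chunk=500, overlap=100)
        assert [(w.start, w.end) for w in wins] == [(0, 500), (400, 900)]

    def test_disjoint_tiling(self):
        wins = kv.split_genome({"chr1": 300}, chunk=100, overlap=0)
        assert [(w.start, w.end) for w in wins] == [(0, 100), (100, 200),
                                                    (200, 300)]

    def test_consecutive_overlap_is_exactly_v(self):
        wins = kv.split_genome({"chr1": 5000}, chunk=400, overlap=150)
        full = [w for w in wins if w.length == 400]
        for a, b in zip(full, full[1:]):
            assert a.end - b.start == 150

    def test_long_tail_emitted_short_window(self):
        wins = kv.split_genome({"chr1": 1200}, chunk=500, overlap=100)
        assert (wins[-1].start, wins[-1].end) == (800, 1200)

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError):
            kv.split_genome({"chr1": 1000}, chunk=100, overlap=100)
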