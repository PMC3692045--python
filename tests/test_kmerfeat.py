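"""Canonical kmer collapsing, feature spaces, count vectors, and kernels.

The independent oracle throughout is plain-Python string counting: enumerate
windows, fold each onto min(kmer, revcomp) with string operations, and
normalize with math.sqrt — no shared code with the vectorized path.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kmersvm as kv

from conftest import random_sequences

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _rc(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def _brute_canonical_count(k: int) -> int:
    return len({min(kmer, _rc(kmer)) for kmer in
                ("".join(t) for t in itertools.product("ACGT", repeat=k))})


def _brute_vector(seq: str, k: int) -> dict[str, float]:
    """Oracle: canonical counts by string ops, L2-normalized."""
    counts: dict[str, int] = {}
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if set(w) - set("ACGT"):
            continue
        c = min(w, _rc(w))
        counts[c] = counts.get(c, 0) + 1
    nrm = math.sqrt(sum(v * v for v in counts.values()))
    return {c: v / nrm for c, v in counts.items()} if nrm else {}


dna = st.text(alphabet="ACGT", min_size=6, max_size=120)


class TestCanonical:
    @pytest.mark.parametrize(
        "kmer,expected",
        [
            ("TTTTTT", "AAAAAA"),
            ("ACGT", "ACGT"),       # palindrome is its own representative
            ("AAGGTC", "AAGGTC"),   # revcomp GACCTT sorts later
            ("GACCTT", "AAGGTC"),
        ],
    )
    def test_examples(self, kmer, expected):
        assert kv.canonical_kmer(kmer) == expected

    @given(dna.filter(lambda s: len(s) <= 12))
    @settings(max_examples=50, derandomize=True)
    def test_idempotent_and_strand_symmetric(self, kmer):
        c = kv.canonical_kmer(kmer)
        assert kv.canonical_kmer(c) == c
        assert kv.canonical_kmer(kv.reverse_complement(kmer)) == c

    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError):
            kv.canonical_kmer("ACGN")


class TestFeatureSpace:
    @pytest.mark.parametrize("k", range(1, 9))
    def test_size_matches_brute_force_enumeration(self, k):
        space = kv.build_feature_space(k)
        assert len(space) == _brute_canonical_count(k)
        # closed form: (4^k + palindromes)/2
        pal = 4 ** (k // 2) if k % 2 == 0 else 0
        assert len(space) == (4**k + pal) // 2

    def test_every_raw_kmer_maps_to_one_canonical(self):
        space = kv.build_feature_space(3)
        kmers = space.kmers
        for raw in ("".join(t) for t in itertools.product("ACGT", repeat=3)):
            assert kmers[space.index_of(raw)] == min(raw, _rc(raw))

    def test_ordering_is_lexicographic_k_ascending(self):
        space = kv.build_feature_space((1, 2))
        assert space.kmers[:2] == ["A", "C"]
        assert space.kmers[2:] == sorted(space.kmers[2:])

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            kv.build_feature_space(0)
        with pytest.raises(ValueError):
            kv.build_feature_space(13)


class TestFeaturize:
    def test_single_kmer_sequence(self, space6):
        fv = kv.featurize("AAAAAA", space6)
        assert fv.values[space6.index_of("AAAAAA")] == 1.0
        assert fv.norm == pytest.approx(1.0)

    def test_worked_dimer_example(self, space2):
        # "ACGTAC": dimers AC, CG, GT->AC, TA, AC => (3,1,1)/sqrt(11)
        fv = kv.featurize("ACGTAC", space2)
        got = {space2.kmers[i]: v for i, v in enumerate(fv.values) if v}
        s11 = math.sqrt(11)
        assert got == pytest.approx({"AC": 3 / s11, "CG": 1 / s11, "TA": 1 / s11})

    def test_matches_brute_force_oracle(self, space6):
        rng = np.random.default_rng(5)
        for seq in random_sequences(rng, 20, 150):
            fv = kv.featurize(seq, space6)
            oracle = _brute_vector(seq, 6)
            got = {space6.kmers[i]: v for i, v in enumerate(fv.values) if v}
            assert set(got) == set(oracle)
            for kmer, v in oracle.items():
                assert got[kmer] == pytest.approx(v, abs=1e-12)

    @given(dna)
    @settings(max_examples=60, derandomize=True)
    def test_strand_invariance_exact(self, seq):
        space = kv.build_feature_space(3)
        a = kv.featurize(seq, space).values
        b = kv.featurize(kv.reverse_complement(seq), space).values
        assert (a == b).all()

    def test_n_windows_skipped(self, space2):
        # "ANGT": only the GT window is countable -> single unit coordinate
        fv = kv.featurize("ANGT", space2)
        assert fv.values[space2.index_of("GT")] == 1.0
        assert fv.norm == pytest.approx(1.0)

    def test_all_n_gives_flagged_zero_vector(self, space6):
        fv = kv.featurize("NNNNNNNN", space6)
        assert fv.norm == 0.0

    def test_short_sequence_zero_vector(self, space6):
        assert kv.featurize("ACG", space6).norm == 0.0


class TestWeightedSpectrum:
    def test_unit_norm_and_block_weighting(self):
        space = kv.build_feature_space((2, 3))
        fv = kv.featurize("ACGTACGTAC", space)
        assert fv.norm == pytest.approx(1.0, abs=1e-12)
        # each block contributes 1/2 of the squared norm
        b2 = space.blocks[0]
        block = fv.values[b2.offset : b2.offset + b2.n_features]
        assert np.dot(block, block) == pytest.approx(0.5, abs=1e-12)


class TestSpectrumKernel:
    def test_self_kernel_is_one(self, space6):
        fv = kv.featurize("ACGTAAGGTCAG", space6)
        assert kv.spectrum_kernel(fv, fv) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_features_give_zero(self, space6):
        a = kv.featurize("AAAAAA", space6)
        b = kv.featurize("CCCCCC", space6)  # canonicalizes to GGGGGG
        assert kv.spectrum_kernel(a, b) == 0.0

    def test_matches_brute_force_kernel(self, space6):
        rng = np.random.default_rng(9)
        seqs = random_sequences(rng, 20, 120)
        for s, t in zip(seqs[::2], seqs[1::2]):
            fa, fb = kv.featurize(s, space6), kv.featurize(t, space6)
            va, vb = _brute_vector(s, 6), _brute_vector(t, 6)
            oracle = sum(va[c] * vb.get(c, 0.0) for c in va)
            assert kv.spectrum_kernel(fa, fb) == pytest.approx(oracle, abs=1e-12)

    def test_mismatched_spaces_rejected(self, space6, space2):
        a = kv.featurize("ACGTACGT", space6)
        b = kv.featurize("ACGTACGT", space2)
        with pytest.raises(ValueError):
            kv.spectrum_kernel(a, b)

    def test_gram_matrix_positive_semidefinite(self, space6):
        rng = np.random.default_rng(13)
        X = kv.featurize_matrix(random_sequences(rng, 30, 80), space6)
        eigvals = np.linalg.eigvalsh(X @ X.T)
        assert eigvals.min() >= -1e-9
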