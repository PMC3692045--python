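"""Strand-collapsed kmer feature spaces, count vectors and spectrum kernels.

Transcription factors bind double-stranded DNA, so a kmer and its reverse
complement describe the same binding site.  Every feature here is therefore a
*canonical* kmer — the lexicographic minimum of the {kmer, reverse-complement}
pair — and each window increments its canonical feature exactly once, so
palindromic kmers are not double-counted.  For length k this yields
(4^k + p(k)) / 2 features, with p(k) = 4^(k/2) palindromes for even k and
none for odd k (an odd-length DNA string cannot equal its reverse complement
because its middle base would have to be self-complementary).

The spectrum kernel between two sequences is the inner product of their
L2-normalized canonical kmer count vectors; the weighted spectrum kernel
concatenates several k with equal weight.  Because the kernel is an explicit
inner product, a linear SVM in this feature space is mathematically the
kernelized SVM, and its primal coefficients are directly the kmer weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np

from .seqio import SequenceRecord

__all__ = [
    "reverse_complement",
    "canonical_kmer",
    "KmerFeatureSpace",
    "FeatureVector",
    "build_feature_space",
    "featurize",
    "featurize_matrix",
    "spectrum_kernel",
]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

# base codes A=0, C=1, G=2, T=3 (lexicographic); 255 marks uncountable
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i
_BASES = "ACGT"

MAX_K = 12  # 4^12 lookup entries ~ 128 MB of int32; beyond that is a config error


def reverse_complement(seq: str) -> str:
    """Reverse complement, preserving case and N."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Collapse a kmer and its reverse complement to one representative.

    The representative is the lexicographically smaller of the pair, so
    ``canonical_kmer`` is idempotent and strand-symmetric:
    ``canonical_kmer(x) == canonical_kmer(reverse_complement(x))``.
    """
    upper = kmer.upper()
    if not upper or set(upper) - set("ACGT"):
        raise ValueError(f"kmer {kmer!r} is not a non-empty ACGT string")
    rc = reverse_complement(upper)
    return upper if upper <= rc else rc


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to base codes (0..3), 255 for N / invalid."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_LUT[arr]


def _revcomp_ids(ids: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse complement of base-4 packed kmer ids."""
    rc = np.zeros_like(ids)
    tmp = ids.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - (tmp % 4))
        tmp //= 4
    return rc


def _kmer_string(kmer_id: int, k: int) -> str:
    chars = []
    for _ in range(k):
        chars.append(_BASES[kmer_id % 4])
        kmer_id //= 4
    return "".join(reversed(chars))


@dataclass
class _KBlock:
    k: int
    offset: int                 # start of this block in the concatenated vector
    n_features: int
    canonical_ids: np.ndarray   # sorted packed ids of canonical kmers
    lut: np.ndarray             # packed id (4^k) -> local feature index, int32


@dataclass
class KmerFeatureSpace:
    """The ordered canonical-kmer alphabet for one k or a range of k.

    Features are ordered k-ascending, lexicographic within k.  ``lut`` maps
    every raw 4^k kmer id to the local index of its canonical representative,
    so counting is a table lookup per window.
    """

    k_values: tuple[int, ...]
    blocks: list[_KBlock] = field(repr=False)
    n_features: int = 0

    def __post_init__(self) -> None:
        self.n_features = sum(b.n_features for b in self.blocks)

    @property
    def kmers(self) -> list[str]:
        """Canonical kmer strings in feature order."""
        out: list[str] = []
        for b in self.blocks:
            out.extend(_kmer_string(int(i), b.k) for i in b.canonical_ids)
        return out

    def index_of(self, kmer: str) -> int:
        """Concatenated-vector coordinate of a kmer (canonicalized first)."""
        canon = canonical_kmer(kmer)
        k = len(canon)
        for b in self.blocks:
            if b.k == k:
                packed = 0
                for ch in canon:
                    packed = packed * 4 + _BASES.index(ch)
                return b.offset + int(b.lut[packed])
        raise KeyError(f"k={k} not in feature space {self.k_values}")

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, KmerFeatureSpace) and other.k_values == self.k_values
        )

    def __len__(self) -> int:
        return self.n_features


def build_feature_space(k_values: Union[int, Iterable[int]]) -> KmerFeatureSpace:
    """Enumerate canonical kmers for each k and build the lookup tables."""
    if isinstance(k_values, int):
        ks: tuple[int, ...] = (k_values,)
    else:
        ks = tuple(k_values)
    if not ks or any(k < 1 or k > MAX_K for k in ks):
        raise ValueError(f"k values must lie in [1, {MAX_K}], got {ks}")
    if len(set(ks)) != len(ks) or list(ks) != sorted(ks):
        raise ValueError(f"k values must be strictly increasing, got {ks}")

    blocks: list[_KBlock] = []
    offset = 0
    for k in ks:
        n_raw = 4**k
        ids = np.arange(n_raw, dtype=np.int64)
        rc = _revcomp_ids(ids, k)
        canon = np.minimum(ids, rc)
        canonical_ids = np.unique(canon)  # sorted == lexicographic order
        lut = np.empty(n_raw, dtype=np.int32)
        # rank of each raw id's canonical form among the canonical ids
        lut[:] = np.searchsorted(canonical_ids, canon)
        blocks.append(
            _KBlock(
                k=k,
                offset=offset,
                n_features=len(canonical_ids),
                canonical_ids=canonical_ids,
                lut=lut,
            )
        )
        offset += len(canonical_ids)
    return KmerFeatureSpace(k_values=ks, blocks=blocks)


@dataclass
class FeatureVector:
    """A normalized canonical-kmer count vector over a feature space.

    Each k-block is independently L2-normalized and scaled by 1/sqrt(#k), so
    a vector with every block populated has unit Euclidean norm.  A sequence
    with no countable window in any block yields the zero vector, flagged via
    ``norm == 0``.
    """

    space: KmerFeatureSpace
    values: np.ndarray

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.values))

    def dot(self, other: "FeatureVector") -> float:
        if self.space != other.space:
            raise ValueError("feature vectors from different feature spaces")
        return float(self.values @ other.values)


def _count_block(codes: np.ndarray, block: _KBlock) -> np.ndarray:
    """Raw canonical counts of one k over an encoded sequence."""
    k = block.k
    n = len(codes)
    counts = np.zeros(block.n_features, dtype=np.float64)
    if n < k:
        return counts
    bad = (codes == 255).astype(np.int64)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    window_bad = cbad[k:] - cbad[:-k]  # N count per window
    clean = np.where(codes == 255, 0, codes).astype(np.int64)
    ids = np.zeros(n - k + 1, dtype=np.int64)
    for j in range(k):
        ids = ids * 4 + clean[j : n - k + 1 + j]
    valid = window_bad == 0
    if valid.any():
        np.add.at(counts, block.lut[ids[valid]], 1.0)
    return counts


def _normalize_blocks(space: KmerFeatureSpace, raw: np.ndarray) -> np.ndarray:
    out = np.zeros_like(raw)
    weight = 1.0 / np.sqrt(len(space.blocks))
    for b in space.blocks:
        sl = slice(b.offset, b.offset + b.n_features)
        block = raw[sl]
        nrm = np.linalg.norm(block)
        if nrm > 0:
            out[sl] = block * (weight / nrm)
    return out


def featurize(
    record: Union[SequenceRecord, str], space: KmerFeatureSpace
) -> FeatureVector:
    """Normalized canonical kmer count vector of one sequence.

    Windows containing N are skipped; counting is case-insensitive (masking
    is metadata for null sampling, not sequence content).  The result is
    exactly strand-invariant: featurize(s) == featurize(revcomp(s)).
    """
    seq = record.sequence if isinstance(record, SequenceRecord) else record
    if not seq:
        raise ValueError("cannot featurize an empty sequence")
    codes = _encode(seq)
    raw = np.concatenate([_count_block(codes, b) for b in space.blocks])
    return FeatureVector(space=space, values=_normalize_blocks(space, raw))


def featurize_matrix(
    records: Sequence[Union[SequenceRecord, str]], space: KmerFeatureSpace
) -> np.ndarray:
    """Stack featurize() outputs into an (n_records, n_features) array."""
    X = np.empty((len(records), space.n_features), dtype=np.float64)
    for i, rec in enumerate(records):
        X[i] = featurize(rec, space).values
    return X


def spectrum_kernel(a: FeatureVector, b: FeatureVector) -> float:
    """Inner product of two normalized kmer count vectors.

    Equals 1 on identical non-degenerate sequences and lies in [0, 1]
    because counts are non-negative.
    """
    return a.dot(b)
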