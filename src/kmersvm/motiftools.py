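"""PWM construction from weighted kmers, log-odds scanning, and motif
comparison.

High-magnitude kmer weights become position weight matrices for inspection
and database matching: each kmer maps to a near-delta PWM whose column puts
probability 1 − 3α on the kmer's base and α elsewhere (pseudocount α keeps
log-odds finite).  PWMs are read and written in MEME minimal format.

``pwm_max_logodds`` scores a sequence by the best log2-odds (bits, against a
background distribution) of the PWM over all positions and both strands —
the classical single-motif scanning baseline the kmer-SVM is compared to.

``pwm_similarity`` aligns two PWMs over all ungapped offsets and both target
orientations and scores the overlap by a column-wise metric: Pearson
correlation of the base-probability columns, negated Euclidean distance, or
the Sandelin–Wasserman column score 2 − Σ(p−q)².  Ranking a query against a
motif database by raw similarity replaces the full statistical machinery of
dedicated motif-comparison tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .kmerfeat import reverse_complement
from .seqio import SequenceRecord

__all__ = [
    "PWM",
    "MotifMatch",
    "kmer_to_pwm",
    "kmers_to_meme",
    "write_meme",
    "read_meme",
    "pwm_max_logodds",
    "pwm_similarity",
    "rank_matches",
]

_BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASE_ORDER)}
MAX_MEME_KMERS = 50       # hard cap on kmers exported per MEME file
UNIFORM_BG = np.full(4, 0.25)


@dataclass
class PWM:
    """A position weight matrix: L columns of base probabilities (A,C,G,T)."""

    name: str
    matrix: np.ndarray            # shape (L, 4), rows sum to 1
    nsites: int = 20
    evalue: float = 0.0
    source_weight: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (L, 4)")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name!r} columns do not sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASE_ORDER[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            name=self.name,
            matrix=self.matrix[::-1, ::-1].copy(),
            nsites=self.nsites,
            evalue=self.evalue,
            source_weight=self.source_weight,
        )


@dataclass
class MotifMatch:
    """Best ungapped alignment of a query PWM against one target PWM."""

    query: str
    target: str
    metric: str
    best_offset: int
    orientation: str        # "forward" | "revcomp"
    similarity: float
    n_columns: int


def kmer_to_pwm(
    kmer: str, alpha: float = 0.01, name: str | None = None,
    source_weight: float | None = None,
) -> PWM:
    """Near-delta PWM for a kmer: 1 − 3α on the consensus base, α elsewhere."""
    if not 0 <= alpha < 1 / 3:
        raise ValueError("pseudocount alpha must lie in [0, 1/3)")
    kmer = kmer.upper()
    if set(kmer) - set(_BASE_ORDER):
        raise ValueError(f"kmer {kmer!r} is not an ACGT string")
    mat = np.full((len(kmer), 4), alpha)
    for i, base in enumerate(kmer):
        mat[i, _BASE_INDEX[base]] = 1.0 - 3.0 * alpha
    return PWM(name=name or kmer, matrix=mat, source_weight=source_weight)


def kmers_to_meme(
    weights: pd.DataFrame,
    n_top: int = 10,
    n_bottom: int = 10,
    alpha: float = 0.01,
) -> str:
    """MEME-format PWMs for the most positive and most negative kmers.

    ``weights`` is the ranked table from
    :func:`kmersvm.svmcore.extract_weights` (columns kmer, weight).  At most
    50 kmers total may be exported.
    """
    if n_top < 0 or n_bottom < 0:
        raise ValueError("kmer counts must be non-negative")
    if n_top + n_bottom > MAX_MEME_KMERS:
        raise ValueError(
            f"requested {n_top + n_bottom} kmers; at most {MAX_MEME_KMERS} "
            "may be exported"
        )
    if len(weights) == 0:
        raise ValueError("empty weights table")
    df = weights.sort_values(["weight", "kmer"], ascending=[False, True])
    chosen = pd.concat([df.head(n_top), df.tail(n_bottom)]).drop_duplicates("kmer")
    pwms = [
        kmer_to_pwm(row.kmer, alpha=alpha, source_weight=float(row.weight))
        for row in chosen.itertuples()
    ]
    return write_meme(pwms)


# ---------------------------------------------------------------------------
# MEME minimal format
# ---------------------------------------------------------------------------

def write_meme(pwms: Sequence[PWM], path: Union[str, Path, None] = None) -> str:
    """Serialize PWMs in MEME minimal motif format (returned; also written
    to `path` when given)."""
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        "A 0.25000 C 0.25000 G 0.25000 T 0.25000",
        "",
    ]
    for pwm in pwms:
        lines.append(f"MOTIF {pwm.name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {len(pwm)} "
            f"nsites= {pwm.nsites} E= {pwm.evalue:g}"
        )
        for row in pwm.matrix:
            lines.append(" ".join(f"{v:.6f}" for v in row))
        lines.append("")
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text


def read_meme(source: Union[str, Path]) -> list[PWM]:
    """Parse MEME minimal format; accepts a path or the text itself."""
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    pwms: list[PWM] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            name = line.split(maxsplit=2)[1]
            i += 1
            nsites, evalue, width = 20, 0.0, None
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability"
            ):
                i += 1
            if i == len(lines):
                raise ValueError(f"MOTIF {name}: missing probability matrix")
            header = lines[i].strip()
            tokens = header.replace("letter-probability matrix:", "").split()
            kv = dict(zip(tokens[::2], tokens[1::2]))
            width = int(kv.get("w=", kv.get("w", 0)) or 0)
            nsites = int(float(kv.get("nsites=", kv.get("nsites", 20)) or 20))
            evalue = float(kv.get("E=", kv.get("E", 0)) or 0)
            i += 1
            rows = []
            while i < len(lines):
                s = lines[i].strip()
                if not s or s.startswith("MOTIF"):
                    break
                rows.append([float(v) for v in s.split()])
                i += 1
            mat = np.array(rows)
            if width and mat.shape[0] != width:
                raise ValueError(
                    f"MOTIF {name}: declared width {width}, found {mat.shape[0]} rows"
                )
            pwms.append(PWM(name=name, matrix=mat, nsites=nsites, evalue=evalue))
        else:
            i += 1
    if not pwms:
        raise ValueError("no MOTIF blocks found in MEME input")
    return pwms


# ---------------------------------------------------------------------------
# Log-odds scanning
# ---------------------------------------------------------------------------

def pwm_max_logodds(
    record: Union[SequenceRecord, str],
    pwm: PWM,
    background: np.ndarray | None = None,
) -> float:
    """Maximum log2-odds (bits) of the PWM over all positions, both strands.

    N positions contribute 0 bits.  A sequence shorter than the motif gets
    -inf (flagged minimal score) so it never outranks a scannable sequence.
    """
    seq = (record.sequence if isinstance(record, SequenceRecord) else record).upper()
    L = len(pwm)
    if len(seq) < L:
        return float("-inf")
    bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)

    with np.errstate(divide="ignore"):
        logodds = np.log2(pwm.matrix / bg)          # (L, 4); -inf where p == 0
        logodds_rc = np.log2(pwm.matrix[::-1, ::-1] / bg)
    # 5th row: N contributes zero bits at any column
    lo = np.vstack([logodds.T, np.zeros(L)]).T      # (L, 5)
    lo_rc = np.vstack([logodds_rc.T, np.zeros(L)]).T

    idx = np.full(len(seq), 4, dtype=np.int64)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for b, i in _BASE_INDEX.items():
        idx[arr == ord(b)] = i

    best = float("-inf")
    for mat in (lo, lo_rc):
        windows = np.lib.stride_tricks.sliding_window_view(idx, L)
        scores = mat[np.arange(L), windows].sum(axis=1)
        m = float(scores.max())
        best = max(best, m)
    return best


# ---------------------------------------------------------------------------
# PWM similarity (column-wise, ungapped)
# ---------------------------------------------------------------------------

def _column_scores(p: np.ndarray, q: np.ndarray, metric: str) -> np.ndarray:
    """Per-column similarity of two aligned (n, 4) probability blocks."""
    if metric == "euclidean":
        return -np.linalg.norm(p - q, axis=1)
    if metric == "sandelin_wasserman":
        return 2.0 - ((p - q) ** 2).sum(axis=1)
    if metric == "pearson":
        pc = p - p.mean(axis=1, keepdims=True)
        qc = q - q.mean(axis=1, keepdims=True)
        num = (pc * qc).sum(axis=1)
        den = np.sqrt((pc**2).sum(axis=1) * (qc**2).sum(axis=1))
        out = np.empty(len(p))
        flat = den == 0
        # a uniform column carries no preference: correlate 1 iff both uniform
        out[~flat] = num[~flat] / den[~flat]
        out[flat] = np.where(
            np.isclose(p[flat], q[flat]).all(axis=1), 1.0, 0.0
        )
        return out
    raise ValueError(f"unknown metric {metric!r}")


def pwm_similarity(
    query: PWM, target: PWM, metric: str = "pearson", min_overlap: int = 4
) -> MotifMatch:
    """Best ungapped alignment of query vs target under a column metric.

    All offsets with at least ``min_overlap`` aligned columns are scanned in
    both target orientations; similarity is the mean per-column score over
    the overlap.  Ties prefer the forward orientation, then the smaller
    offset.
    """
    lq, lt = len(query), len(target)
    if min(lq, lt) < min_overlap:
        raise ValueError(
            f"motifs of widths {lq} and {lt} cannot overlap by {min_overlap} columns"
        )
    best: MotifMatch | None = None
    for orientation, tgt in (("forward", target), ("revcomp",
                                                   target.reverse_complement())):
        for offset in range(-(lq - min_overlap), lt - min_overlap + 1):
            qs = max(0, -offset)
            ts = max(0, offset)
            n = min(lq - qs, lt - ts)
            if n < min_overlap:
                continue
            score = float(
                _column_scores(
                    query.matrix[qs : qs + n], tgt.matrix[ts : ts + n], metric
                ).mean()
            )
            if best is None or score > best.similarity + 1e-15:
                best = MotifMatch(
                    query=query.name, target=target.name, metric=metric,
                    best_offset=offset, orientation=orientation,
                    similarity=score, n_columns=n,
                )
    assert best is not None
    return best


def rank_matches(
    query: PWM, database: Iterable[PWM], metric: str = "pearson",
    min_overlap: int = 4,
) -> list[MotifMatch]:
    """Rank database motifs by similarity to the query, best first.

    Ties break deterministically on target name.
    """
    db = list(database)
    if not db:
        raise ValueError("empty motif database")
    matches = [pwm_similarity(query, t, metric, min_overlap) for t in db]
    return sorted(matches, key=lambda m: (-m.similarity, m.target))
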