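"""Sequence and interval I/O, sequence profiles, and the genome index.

This module handles the two interchange formats of the pipeline — soft-masked
FASTA and BED3+ (0-based, half-open) — and computes the "sequence profile" of
a region set: the per-region length, GC fraction and repeat fraction, whose
joint distributions are the matching target for null-set generation.

Conventions
-----------
* Lowercase bases mark soft-masked (repeat-annotated) sequence; the repeat
  fraction of a window is its lowercase fraction.
* GC fraction is computed over non-N bases only.  An all-N window has an
  undefined GC fraction and is flagged rather than raising.
* Non-ACGTN IUPAC codes are mapped to N with a warning on ingestion.
"""

from __future__ import annotations

import hashlib
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, Union

import numpy as np

__all__ = [
    "GenomicInterval",
    "SequenceRecord",
    "RecordProfile",
    "SequenceProfile",
    "GenomeIndex",
    "FastaParseError",
    "BedParseError",
    "CoordinateError",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "load_genome",
    "extract_sequences",
    "compute_profile",
    "profile_report",
    "build_genome_index",
]


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


class BedParseError(ValueError):
    """Raised for malformed BED input; message names the offending line."""


class CoordinateError(ValueError):
    """Raised when an interval does not fit on its chromosome."""


# Non-ACGTN IUPAC ambiguity codes are tolerated but collapsed to N
# (case preserved so masking information survives).
_IUPAC_AMBIGUOUS = "RYSWKMBDHVryswkmbdhv"
_AMBIG_TO_N = str.maketrans(
    _IUPAC_AMBIGUOUS, "N" * 10 + "n" * 10
)
_VALID_BASES = frozenset("ACGTNacgtn")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic coordinate range [start, end) on `chrom`.

    Coordinates follow the standard BED dialect: 0-based start (inclusive),
    0-based end (exclusive).
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N}; lowercase marks soft-masking."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            cleaned = self.sequence.translate(_AMBIG_TO_N)
            still_bad = set(cleaned) - _VALID_BASES
            if still_bad:
                raise ValueError(
                    f"record {self.id!r} contains non-IUPAC characters "
                    f"{sorted(still_bad)!r}"
                )
            warnings.warn(
                f"record {self.id!r}: ambiguous IUPAC codes {sorted(bad)!r} "
                "mapped to N",
                stacklevel=2,
            )
            self.sequence = cleaned

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RecordProfile:
    """Length / GC / repeat triple for one sequence.

    ``gc_defined`` is False for all-N sequences, where GC has no denominator;
    ``gc`` is then reported as 0.0.
    """

    length: int
    gc: float
    repeat: float
    gc_defined: bool = True


@dataclass
class SequenceProfile:
    """Per-record profiles of a region set plus convenience summaries."""

    ids: list[str]
    lengths: np.ndarray
    gc: np.ndarray
    repeat: np.ndarray

    @property
    def mean_gc(self) -> float:
        return float(np.mean(self.gc))

    @property
    def mean_length(self) -> float:
        return float(np.mean(self.lengths))

    @property
    def mean_repeat(self) -> float:
        return float(np.mean(self.repeat))

    def histograms(self, bins: int = 20) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Empirical histograms (counts, bin_edges) of the three profile axes."""
        return {
            "length": np.histogram(self.lengths, bins=bins),
            "gc": np.histogram(self.gc, bins=bins, range=(0.0, 1.0)),
            "repeat": np.histogram(self.repeat, bins=bins, range=(0.0, 1.0)),
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "id": self.ids,
                "length": self.lengths,
                "gc": self.gc,
                "repeat": self.repeat,
            }
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> list[SequenceRecord]:
    """Parse a FASTA file, preserving case (soft-masking).

    Record ids are the header token up to the first whitespace.  Malformed
    input raises :class:`FastaParseError` naming the line number.
    """
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(
                f"{path}: record {header!r} (line {header_line}) has no sequence"
            )
        records.append(SequenceRecord(header, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                _flush()
                token = line[1:].split()
                if not token:
                    raise FastaParseError(f"{path}: empty header at line {lineno}")
                header = token[0]
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}: sequence before any header at line {lineno}"
                    )
                chunks.append(line.strip())
    _flush()
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: Union[str, Path], width: int = 60
) -> None:
    """Write records as FASTA, wrapping sequence lines at `width` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


GenomeLike = Union[str, Path, Mapping[str, str], Sequence[SequenceRecord]]


def load_genome(genome: GenomeLike) -> dict[str, str]:
    """Normalize a genome argument to a {chrom: sequence} mapping.

    Accepts a FASTA path, a mapping, or a list of records.  Genomes are held
    in memory; the tool targets region-set analysis where even a mammalian
    soft-masked genome fits comfortably, and toy genomes trivially so.
    """
    if isinstance(genome, (str, Path)):
        return {rec.id: rec.sequence for rec in read_fasta(genome)}
    if isinstance(genome, Mapping):
        return dict(genome)
    return {rec.id: rec.sequence for rec in genome}


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: Union[str, Path]) -> list[GenomicInterval]:
    """Parse a BED3+ file into intervals (0-based, half-open).

    Columns beyond the first three populate name/score/strand when present.
    Validation failures raise :class:`BedParseError` with the line number.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(
                        f"{path}: line {lineno}: non-numeric score"
                    ) from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, name, score, strand)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: Union[str, Path]) -> None:
    """Write intervals as BED, emitting optional columns only when present."""
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            has_extra = (
                iv.name is not None or iv.score is not None or iv.strand != "."
            )
            if has_extra:
                fields.append(iv.name if iv.name is not None else ".")
                fields.append(
                    format(iv.score, "g") if iv.score is not None else "0"
                )
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Extraction and profiles
# ---------------------------------------------------------------------------

def extract_sequences(
    intervals: Iterable[GenomicInterval], genome: GenomeLike
) -> list[SequenceRecord]:
    """Fetch interval sequences from a genome, preserving case.

    Record ids encode the coordinates as ``chrom:start-end`` (the interval's
    own name, when set, is appended after a ``|``).
    """
    chroms = load_genome(genome)
    out: list[SequenceRecord] = []
    for iv in intervals:
        seq = chroms.get(iv.chrom)
        if seq is None:
            raise CoordinateError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > len(seq):
            raise CoordinateError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {len(seq)}"
            )
        rid = f"{iv.chrom}:{iv.start}-{iv.end}"
        if iv.name:
            rid = f"{rid}|{iv.name}"
        out.append(SequenceRecord(rid, seq[iv.start : iv.end]))
    return out


def compute_profile(record: Union[SequenceRecord, str]) -> RecordProfile:
    """Length, GC fraction and repeat (soft-masked) fraction of one sequence.

    GC is counted case-insensitively over non-N bases; repeat fraction is the
    lowercase fraction of the full length.
    """
    seq = record.sequence if isinstance(record, SequenceRecord) else record
    if not seq:
        raise ValueError("cannot profile an empty sequence")
    n_total = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    upper = arr & ~np.uint8(0x20)  # fold case: 'a'->'A' etc.
    is_n = upper == ord("N")
    is_gc = (upper == ord("G")) | (upper == ord("C"))
    is_lower = (arr >= ord("a")) & (arr <= ord("z"))
    n_n = int(is_n.sum())
    denom = n_total - n_n
    if denom == 0:
        return RecordProfile(n_total, 0.0, float(is_lower.mean()), gc_defined=False)
    gc = float(is_gc.sum()) / denom
    repeat = float(is_lower.sum()) / n_total
    return RecordProfile(n_total, gc, repeat)


def profile_report(
    intervals: Iterable[GenomicInterval], genome: GenomeLike
) -> SequenceProfile:
    """Sequence profile of a region set: per-region (length, gc, repeat)."""
    records = extract_sequences(intervals, genome)
    profs = [compute_profile(r) for r in records]
    return SequenceProfile(
        ids=[r.id for r in records],
        lengths=np.array([p.length for p in profs], dtype=np.int64),
        gc=np.array([p.gc for p in profs], dtype=float),
        repeat=np.array([p.repeat for p in profs], dtype=float),
    )


# ---------------------------------------------------------------------------
# Genome index
# ---------------------------------------------------------------------------

@dataclass
class _ChromIndex:
    length: int
    gc: np.ndarray      # prefix sums of G/C count (len+1, int64)
    mask: np.ndarray    # prefix sums of lowercase count
    n: np.ndarray       # prefix sums of N count


@dataclass
class GenomeIndex:
    """Per-chromosome prefix sums of GC / masked / N base counts.

    Gives O(1) window statistics for any [start, end) window, which is what
    makes rejection sampling of profile-matched null windows cheap: each
    candidate window is tested from the prefix sums without touching the
    sequence itself.
    """

    chroms: dict[str, _ChromIndex] = field(default_factory=dict)
    checksum: str = ""

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: ci.length for name, ci in self.chroms.items()}

    def _chrom(self, chrom: str) -> _ChromIndex:
        try:
            return self.chroms[chrom]
        except KeyError:
            raise CoordinateError(f"unknown chromosome {chrom!r}") from None

    def window_counts(self, chrom: str, start: int, end: int) -> tuple[int, int, int]:
        """(gc_count, masked_count, n_count) for the window, exact integers."""
        ci = self._chrom(chrom)
        if start < 0 or end > ci.length or start >= end:
            raise CoordinateError(
                f"window {chrom}:{start}-{end} invalid on length {ci.length}"
            )
        return (
            int(ci.gc[end] - ci.gc[start]),
            int(ci.mask[end] - ci.mask[start]),
            int(ci.n[end] - ci.n[start]),
        )

    def window_profile(self, chrom: str, start: int, end: int) -> RecordProfile:
        """RecordProfile of a window, identical to direct recomputation."""
        gc_count, mask_count, n_count = self.window_counts(chrom, start, end)
        length = end - start
        denom = length - n_count
        if denom == 0:
            return RecordProfile(length, 0.0, mask_count / length, gc_defined=False)
        return RecordProfile(length, gc_count / denom, mask_count / length)

    def window_stats_batch(
        self, chrom: str, starts: np.ndarray, length: int
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized (gc, repeat, n_fraction) for equal-length windows.

        GC for all-N windows is returned as NaN.
        """
        ci = self._chrom(chrom)
        ends = starts + length
        gc_counts = ci.gc[ends] - ci.gc[starts]
        mask_counts = ci.mask[ends] - ci.mask[starts]
        n_counts = ci.n[ends] - ci.n[starts]
        denom = length - n_counts
        with np.errstate(divide="ignore", invalid="ignore"):
            gc = np.where(denom > 0, gc_counts / np.maximum(denom, 1), np.nan)
        return gc, mask_counts / length, n_counts / length


def build_genome_index(genome: GenomeLike) -> GenomeIndex:
    """Build prefix-sum tables for GC, masked and N counts per chromosome."""
    chroms = load_genome(genome)
    index = GenomeIndex()
    hasher = hashlib.sha256()
    for name in chroms:
        seq = chroms[name]
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        upper = arr & ~np.uint8(0x20)
        is_gc = (upper == ord("G")) | (upper == ord("C"))
        is_n = upper == ord("N")
        is_lower = (arr >= ord("a")) & (arr <= ord("z"))

        def _prefix(mask: np.ndarray) -> np.ndarray:
            out = np.zeros(len(mask) + 1, dtype=np.int64)
            np.cumsum(mask, out=out[1:])
            return out

        index.chroms[name] = _ChromIndex(
            length=len(seq),
            gc=_prefix(is_gc),
            mask=_prefix(is_lower),
            n=_prefix(is_n),
        )
        hasher.update(name.encode())
        hasher.update(seq.encode("ascii"))
    index.checksum = hasher.hexdigest()
    return index
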