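"""Seeded synthetic fixtures: toy genomes and planted-motif sequence sets.

Real training data for this pipeline are ChIP-seq/DNase-seq peak sets; the
generator stands in for them with a fully controlled analogue.  Background is
i.i.d. sequence at a specified GC fraction; positive sequences carry each
"positive-enriched" consensus kmer planted once (uniform random position,
random strand) with its planting probability, while "negative-only" motifs
are planted only in the negatives — emulating repressive elements whose
absence is what marks a region as positive.  Toy genomes additionally carry
contiguous lowercase (soft-masked) stretches so that repeat-fraction matching
is exercised.

Everything is driven by one seeded PRNG, so identical configs produce
byte-identical FASTA output, and ground truth (planted positions and strands)
is returned for oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqio import SequenceRecord

__all__ = [
    "MotifSpec",
    "ChromosomeSpec",
    "SyntheticConfig",
    "LabeledSets",
    "generate_toy_genome",
    "generate_labeled_sets",
    "default_benchmark_config",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class MotifSpec:
    """One planted consensus kmer.

    role: "positive" motifs are planted in positive sequences with
    probability ``p_plant``; "negative_only" motifs are planted only in
    negative sequences (a repressor-like feature).
    """

    consensus: str
    p_plant: float
    role: str = "positive"

    def __post_init__(self) -> None:
        if set(self.consensus.upper()) - set("ACGT"):
            raise ValueError(f"consensus {self.consensus!r} must be ACGT")
        if not 0 <= self.p_plant <= 1:
            raise ValueError("planting probability must lie in [0, 1]")
        if self.role not in ("positive", "negative_only"):
            raise ValueError(f"unknown motif role {self.role!r}")


@dataclass(frozen=True)
class ChromosomeSpec:
    name: str
    length: int
    masked_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("chromosome length must be >= 1")
        if not 0 <= self.masked_fraction <= 1:
            raise ValueError("masked fraction must lie in [0, 1]")


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    Defaults mirror a short-TF-peak setup: 1000 positive 100-bp elements at
    genomic GC ≈ 0.42, one 6-bp consensus planted in 90% of positives, and a
    10× negative set.
    """

    n_pos: int = 1000
    seq_length: int = 100
    motifs: Sequence[MotifSpec] = field(
        default_factory=lambda: (MotifSpec("AAGGTC", 0.9),)
    )
    gc_background: float = 0.42
    fold_negatives: int = 10
    seed: int = 1
    require_at_least_one: bool = False
    genome_spec: Sequence[ChromosomeSpec] = field(
        default_factory=lambda: (
            ChromosomeSpec("chrA", 1_000_000, 0.10),
            ChromosomeSpec("chrB", 1_000_000, 0.10),
        )
    )

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.seq_length < 1:
            raise ValueError("n_pos and seq_length must be positive")
        if not 0 < self.gc_background < 1:
            raise ValueError("gc_background must lie in (0, 1)")
        longest = max((len(m.consensus) for m in self.motifs), default=0)
        if longest > self.seq_length:
            raise ValueError("seq_length shorter than the longest motif")


@dataclass
class LabeledSets:
    positives: list[SequenceRecord]
    negatives: list[SequenceRecord]
    truth: list[dict]      # one entry per planted occurrence


def _random_background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """i.i.d. bases with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2, as uint8 codes."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def generate_toy_genome(
    config: SyntheticConfig | None = None,
    genome_spec: Sequence[ChromosomeSpec] | None = None,
    gc_background: float | None = None,
    seed: int | None = None,
    mask_stretch: int = 500,
) -> dict[str, str]:
    """Multi-chromosome toy genome: i.i.d. background plus soft-masked
    stretches.

    Masking is laid down as non-overlapping runs of ``mask_stretch`` bp at
    seeded random positions until the per-chromosome masked fraction is
    reached, approximating the clustered layout of real repeat annotation.
    """
    config = config or SyntheticConfig()
    spec = genome_spec if genome_spec is not None else config.genome_spec
    gc = gc_background if gc_background is not None else config.gc_background
    rng = np.random.default_rng(config.seed if seed is None else seed)

    genome: dict[str, str] = {}
    for chrom in spec:
        codes = _random_background(rng, chrom.length, gc)
        seq = _BASES[codes].tobytes().decode("ascii")
        target_masked = int(round(chrom.masked_fraction * chrom.length))
        if target_masked > 0:
            masked = np.zeros(chrom.length, dtype=bool)
            total = 0
            attempts = 0
            while total < target_masked and attempts < 100_000:
                attempts += 1
                run = min(mask_stretch, target_masked - total)
                if run > chrom.length:
                    run = chrom.length
                start = int(rng.integers(0, chrom.length - run + 1))
                if masked[start : start + run].any():
                    continue
                masked[start : start + run] = True
                total += run
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
            arr[masked] |= 0x20  # lowercase
            seq = arr.tobytes().decode("ascii")
        genome[chrom.name] = seq
    return genome


def _plant(
    rng: np.random.Generator,
    codes: np.ndarray,
    motif: str,
    occupied: list[tuple[int, int]],
) -> tuple[int, str] | None:
    """Plant one occurrence at a uniform free position, random strand."""
    from .kmerfeat import reverse_complement

    L = len(motif)
    n = len(codes)
    strand = "+" if rng.random() < 0.5 else "-"
    inserted = motif if strand == "+" else reverse_complement(motif)
    ins_codes = np.array(
        [_BASES.tobytes().decode().index(b) for b in inserted], dtype=np.uint8
    )
    for _ in range(200):
        start = int(rng.integers(0, n - L + 1))
        if any(start < e and s < start + L for s, e in occupied):
            continue
        codes[start : start + L] = ins_codes
        occupied.append((start, start + L))
        return start, strand
    return None


def generate_labeled_sets(config: SyntheticConfig | None = None) -> LabeledSets:
    """Planted-motif positive set and background negative set.

    Positives receive each positive-role motif independently with its
    planting probability (once, uniform position, random strand);
    negative-only motifs are planted in negatives the same way.  With
    ``require_at_least_one`` the positive-motif indicator draw is redone
    until at least one positive-role motif lands — modelling region sets
    defined by the presence of any one of several accessory sites.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    pos_motifs = [m for m in config.motifs if m.role == "positive"]
    neg_motifs = [m for m in config.motifs if m.role == "negative_only"]
    if config.require_at_least_one and not pos_motifs:
        raise ValueError("require_at_least_one needs at least one positive motif")

    truth: list[dict] = []
    positives: list[SequenceRecord] = []
    for i in range(config.n_pos):
        codes = _random_background(rng, config.seq_length, config.gc_background)
        occupied: list[tuple[int, int]] = []
        for _ in range(1000):
            plant_flags = [rng.random() < m.p_plant for m in pos_motifs]
            if not config.require_at_least_one or any(plant_flags) or not pos_motifs:
                break
        else:
            raise RuntimeError("could not satisfy require_at_least_one")
        for m, do_plant in zip(pos_motifs, plant_flags):
            if not do_plant:
                continue
            hit = _plant(rng, codes, m.consensus, occupied)
            if hit is None:
                raise ValueError(
                    f"could not place {m.consensus} in a {config.seq_length} bp "
                    "sequence without overlap"
                )
            truth.append(
                {"set": "positive", "seq": f"pos_{i}", "motif": m.consensus,
                 "position": hit[0], "strand": hit[1]}
            )
        positives.append(SequenceRecord(f"pos_{i}", _codes_to_str(codes)))

    n_neg = config.fold_negatives * config.n_pos
    negatives: list[SequenceRecord] = []
    for i in range(n_neg):
        codes = _random_background(rng, config.seq_length, config.gc_background)
        occupied = []
        for m in neg_motifs:
            if rng.random() < m.p_plant:
                hit = _plant(rng, codes, m.consensus, occupied)
                if hit is None:
                    raise ValueError(
                        f"could not place {m.consensus} in a "
                        f"{config.seq_length} bp sequence without overlap"
                    )
                truth.append(
                    {"set": "negative", "seq": f"neg_{i}", "motif": m.consensus,
                     "position": hit[0], "strand": hit[1]}
                )
        negatives.append(SequenceRecord(f"neg_{i}", _codes_to_str(codes)))

    return LabeledSets(positives=positives, negatives=negatives, truth=truth)


def default_benchmark_config(seed: int = 1) -> SyntheticConfig:
    """The standard single-motif benchmark: 1000 positives, 100 bp, AAGGTC
    planted at 0.9, GC 0.42, 10× negatives."""
    return SyntheticConfig(seed=seed)
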