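"""Profile-matched null (negative) sequence set generation.

A classifier trained on experimentally derived regions against arbitrary
genomic background would partly learn composition biases — GC content, region
length, repeat content — rather than binding-site vocabulary.  The null
generator removes that confound: for each requested negative it picks a
positive region (cycling through positives in a seeded random order), then
rejection-samples windows *on the same chromosome* of exactly the positive's
length until one matches the positive's GC and repeat fractions within the
configured tolerances and overlaps no positive, excluded, or previously
accepted interval by even one base pair.

Window statistics come from the prefix-sum :class:`~kmersvm.seqio.GenomeIndex`
(O(1) per candidate), so even tight tolerances are tractable.  If rejection
sampling exhausts ``max_attempts`` draws for a positive, the sampler falls
back to an exhaustive chunked scan of every start on the chromosome and picks
uniformly among the in-tolerance, non-overlapping windows — so a matchable
positive is always matched *within* tolerance.  Only when no such window
exists at all are the tolerances doubled once (the accepted negative is then
marked ``relaxed`` in the report); a positive that still fails is skipped
with a warning.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .seqio import GenomeIndex, GenomicInterval

__all__ = [
    "NullGenConfig",
    "NullSetResult",
    "MatchQualityReport",
    "generate_null_set",
    "match_quality",
]

_BATCH = 256  # candidate starts drawn per vectorized rejection round


@dataclass
class NullGenConfig:
    """Configuration for null-set generation.

    fold_increase     negative set size as a multiple of the positive count.
    gc_tolerance      max |GC_neg − GC_pos| (absolute fraction).
    repeat_tolerance  max |repeat_neg − repeat_pos| (absolute fraction).
    seed              PRNG seed; identical config+inputs give identical BED.
    excluded          extra intervals negatives must not overlap.
    max_attempts      draws per negative before the one-time tolerance
                      doubling; the same budget again before skipping.
    max_n_fraction    windows with more N than this are ineligible.
    """

    fold_increase: int = 10
    gc_tolerance: float = 0.02
    repeat_tolerance: float = 0.02
    seed: int = 1
    excluded: Sequence[GenomicInterval] = field(default_factory=tuple)
    max_attempts: int = 10_000
    max_n_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.fold_increase < 1:
            raise ValueError("fold_increase must be >= 1")
        for name in ("gc_tolerance", "repeat_tolerance"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")


@dataclass
class NullSetResult:
    """Negatives plus a per-negative report and skip accounting."""

    negatives: list[GenomicInterval]
    report: pd.DataFrame       # chrom,start,end,source_positive,gc,repeat,attempts
    n_requested: int
    skipped: list[str]         # source-positive labels that could not be matched

    def __iter__(self):
        return iter(self.negatives)

    def __len__(self) -> int:
        return len(self.negatives)


class _BlockedIntervals:
    """Per-chromosome sorted, disjoint interval lists with O(log n) overlap
    checks.

    Inserts merge with any overlapping or touching neighbours, so the stored
    list stays disjoint even when the seeded intervals (e.g. positives)
    overlap each other; a candidate then overlaps iff it overlaps one of its
    two sorted neighbours.
    """

    def __init__(self) -> None:
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}

    def add(self, chrom: str, start: int, end: int) -> None:
        ivs = self._by_chrom.setdefault(chrom, [])
        i = bisect_left(ivs, (start, end))
        lo, hi = start, end
        j0 = i
        while j0 > 0 and ivs[j0 - 1][1] >= lo:
            j0 -= 1
            lo = min(lo, ivs[j0][0])
            hi = max(hi, ivs[j0][1])
        j1 = i
        while j1 < len(ivs) and ivs[j1][0] <= hi:
            hi = max(hi, ivs[j1][1])
            j1 += 1
        ivs[j0:j1] = [(lo, hi)]

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        ivs = self._by_chrom.get(chrom)
        if not ivs:
            return False
        i = bisect_left(ivs, (start, end))
        if i < len(ivs) and ivs[i][0] < end:
            return True
        return i > 0 and ivs[i - 1][1] > start


def generate_null_set(
    positives: Sequence[GenomicInterval],
    index: GenomeIndex,
    config: NullGenConfig | None = None,
) -> NullSetResult:
    """Sample fold_increase × |positives| profile-matched negative intervals.

    Every negative shares its source positive's chromosome and exact length,
    matches its GC and repeat fractions within tolerance, and overlaps no
    positive, excluded, or previously accepted interval.
    """
    config = config or NullGenConfig()
    if not positives:
        raise ValueError("positive set is empty")

    blocked = _BlockedIntervals()
    for iv in list(positives) + list(config.excluded):
        blocked.add(iv.chrom, iv.start, iv.end)

    # eligible-sequence sanity check: total requested bp vs unblocked genome
    total_need = config.fold_increase * sum(iv.length for iv in positives)
    genome_bp = sum(index.chrom_lengths.values())
    blocked_bp = sum(iv.length for iv in list(positives) + list(config.excluded))
    if total_need > 0.5 * (genome_bp - blocked_bp):
        warnings.warn(
            f"requesting {total_need} bp of negatives from ~{genome_bp - blocked_bp} "
            "bp of unblocked genome; expect skips",
            stacklevel=2,
        )

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(positives))
    target = config.fold_increase * len(positives)

    # positive profiles from the index (exact, same arithmetic as candidates)
    pos_profiles = [
        index.window_profile(iv.chrom, iv.start, iv.end) for iv in positives
    ]

    negatives: list[GenomicInterval] = []
    rows: list[tuple] = []
    skipped: list[str] = []
    visit = 0
    while len(negatives) < target and visit < target:
        pidx = int(order[visit % len(order)])
        visit += 1
        piv = positives[pidx]
        prof = pos_profiles[pidx]
        source = piv.name or f"{piv.chrom}:{piv.start}-{piv.end}"

        hit = _sample_one(rng, index, blocked, piv, prof, config)
        if hit is None:
            skipped.append(source)
            warnings.warn(
                f"no profile-matched window found for positive {source} "
                f"after tolerance relaxation; skipping",
                stacklevel=2,
            )
            continue
        start, gc, rpt, attempts, relaxed = hit
        neg = GenomicInterval(
            piv.chrom, start, start + piv.length, name=f"null_{len(negatives)}"
        )
        blocked.add(neg.chrom, neg.start, neg.end)
        negatives.append(neg)
        rows.append(
            (neg.chrom, neg.start, neg.end, source, gc, rpt, attempts, relaxed)
        )

    report = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "source_positive", "gc", "repeat",
                 "attempts", "relaxed"],
    )
    return NullSetResult(
        negatives=negatives, report=report, n_requested=target, skipped=skipped
    )


_SCAN_CHUNK = 5_000_000  # starts per exhaustive-scan chunk (memory bound)


def _sample_one(rng, index, blocked, piv, prof, config):
    """Find one matched window; returns (start, gc, rpt, attempts, relaxed).

    Strategy per tolerance level (base, then doubled once): rejection-sample
    up to max_attempts uniform starts, then scan every start on the
    chromosome exhaustively and choose uniformly among the eligible
    non-overlapping windows.
    """
    chrom_len = index.chrom_lengths[piv.chrom]
    L = piv.length
    if chrom_len < L:
        return None
    for relaxed, (gc_tol, rpt_tol) in enumerate(
        (
            (config.gc_tolerance, config.repeat_tolerance),
            (2 * config.gc_tolerance, 2 * config.repeat_tolerance),
        )
    ):
        attempts = 0
        while attempts < config.max_attempts:
            n_draw = min(_BATCH, config.max_attempts - attempts)
            starts = rng.integers(0, chrom_len - L + 1, size=n_draw)
            gc, rpt, nfrac = index.window_stats_batch(piv.chrom, starts, L)
            ok = (
                (nfrac <= config.max_n_fraction)
                & ~np.isnan(gc)
                & (np.abs(gc - prof.gc) <= gc_tol)
                & (np.abs(rpt - prof.repeat) <= rpt_tol)
            )
            for j in np.flatnonzero(ok):
                s = int(starts[j])
                attempts_used = attempts + int(j) + 1
                if not blocked.overlaps(piv.chrom, s, s + L):
                    return (s, float(gc[j]), float(rpt[j]), attempts_used,
                            bool(relaxed))
            attempts += n_draw
        hit = _exhaustive_scan(
            rng, index, blocked, piv.chrom, L, prof, gc_tol, rpt_tol, config
        )
        if hit is not None:
            s, gc_v, rpt_v = hit
            return s, gc_v, rpt_v, config.max_attempts, bool(relaxed)
    return None


def _exhaustive_scan(rng, index, blocked, chrom, L, prof, gc_tol, rpt_tol,
                     config):
    """Uniform choice among *all* eligible windows on the chromosome.

    Scans starts in chunks via the prefix sums, pools the in-tolerance
    candidates, and tries them in seeded random order until one clears the
    overlap check.  Returns None only when no eligible window exists.
    """
    chrom_len = index.chrom_lengths[chrom]
    candidates: list[np.ndarray] = []
    for lo in range(0, chrom_len - L + 1, _SCAN_CHUNK):
        hi = min(lo + _SCAN_CHUNK, chrom_len - L + 1)
        starts = np.arange(lo, hi, dtype=np.int64)
        gc, rpt, nfrac = index.window_stats_batch(chrom, starts, L)
        ok = (
            (nfrac <= config.max_n_fraction)
            & ~np.isnan(gc)
            & (np.abs(gc - prof.gc) <= gc_tol)
            & (np.abs(rpt - prof.repeat) <= rpt_tol)
        )
        candidates.append(starts[ok])
    cand = np.concatenate(candidates) if candidates else np.empty(0, np.int64)
    if len(cand) == 0:
        return None
    for i in rng.permutation(len(cand)):
        s = int(cand[i])
        if not blocked.overlaps(chrom, s, s + L):
            gc, rpt, _ = index.window_stats_batch(chrom, np.array([s]), L)
            return s, float(gc[0]), float(rpt[0])
    return None


@dataclass
class MatchQualityReport:
    """How closely a negative set reproduces the positive sequence profile."""

    ks_length: float
    ks_gc: float
    ks_repeat: float
    tolerance_pass_rate: float
    per_negative: pd.DataFrame   # id, length, gc, repeat, gc_ok, repeat_ok

    def summary(self) -> str:
        return (
            f"KS(length)={self.ks_length:.4f} KS(gc)={self.ks_gc:.4f} "
            f"KS(repeat)={self.ks_repeat:.4f} "
            f"tolerance pass rate={self.tolerance_pass_rate:.1%}"
        )


def match_quality(
    positives: Sequence[GenomicInterval],
    negatives: Sequence[GenomicInterval],
    index: GenomeIndex,
    config: NullGenConfig | None = None,
    sources: Sequence[str] | None = None,
) -> MatchQualityReport:
    """KS distances between positive/negative profile distributions plus
    per-negative tolerance checks.

    When negatives came from :func:`generate_null_set`, pass the report's
    ``source_positive`` column as ``sources`` so each negative is checked
    against its own source positive; otherwise each negative is checked
    against the nearest positive profile (most favourable assignment).
    """
    if not positives or not negatives:
        raise ValueError("both interval sets must be non-empty")
    config = config or NullGenConfig()

    pos_prof = [index.window_profile(iv.chrom, iv.start, iv.end) for iv in positives]
    neg_prof = [index.window_profile(iv.chrom, iv.start, iv.end) for iv in negatives]
    by_source = {
        (iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"): p
        for iv, p in zip(positives, pos_prof)
    }

    rows = []
    for i, (iv, p) in enumerate(zip(negatives, neg_prof)):
        if sources is not None:
            ref = by_source[sources[i]]
            d_gc = abs(p.gc - ref.gc)
            d_rpt = abs(p.repeat - ref.repeat)
        else:
            d_gc = min(abs(p.gc - q.gc) for q in pos_prof)
            d_rpt = min(abs(p.repeat - q.repeat) for q in pos_prof)
        rows.append(
            (
                iv.name or f"{iv.chrom}:{iv.start}-{iv.end}",
                p.length, p.gc, p.repeat,
                d_gc <= config.gc_tolerance,
                d_rpt <= config.repeat_tolerance,
            )
        )
    per_neg = pd.DataFrame(
        rows, columns=["id", "length", "gc", "repeat", "gc_ok", "repeat_ok"]
    )
    pass_rate = float((per_neg["gc_ok"] & per_neg["repeat_ok"]).mean())

    def _ks(a, b) -> float:
        return float(ks_2samp(a, b, method="asymp").statistic)

    return MatchQualityReport(
        ks_length=_ks([p.length for p in pos_prof], [p.length for p in neg_prof]),
        ks_gc=_ks([p.gc for p in pos_prof], [p.gc for p in neg_prof]),
        ks_repeat=_ks([p.repeat for p in pos_prof], [p.repeat for p in neg_prof]),
        tolerance_pass_rate=pass_rate,
        per_negative=per_neg,
    )
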