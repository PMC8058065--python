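"""Core genomic-interval engine.

All coordinates are 0-based, half-open (BED convention). Interval sets are
kept sorted by (chrom, start, end). The module provides the primitives every
downstream stage builds on: merging, base-pair overlap, summit reduction,
TSS distance, and the background-constrained shuffle used for permutation
null models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "GenomeLayout",
    "GenomicInterval",
    "IntervalSet",
    "merge",
    "intersect_length",
    "summit_point",
    "distance_to_tss",
    "constrained_shuffle",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered map of chromosome name -> length in bp."""

    chromosomes: Mapping[str, int]

    def __post_init__(self) -> None:
        chroms = dict(self.chromosomes)
        if len(chroms) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for name, length in chroms.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "chromosomes", chroms)

    @property
    def total_length(self) -> int:
        return sum(self.chromosomes.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def length(self, chrom: str) -> int:
        try:
            return self.chromosomes[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open region [start, end) on a named chromosome.

    ``summit``, when set, is a 0-based offset from ``start`` and must fall
    inside the interval.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    summit: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.summit is not None and not 0 <= self.summit < self.end - self.start:
            raise ValueError(
                f"summit offset {self.summit} outside interval of width {self.width}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def _sort_key(iv: GenomicInterval) -> tuple[str, int, int]:
    return (iv.chrom, iv.start, iv.end)


@dataclass
class IntervalSet:
    """A sequence of intervals, kept sorted by (chrom, start, end)."""

    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=_sort_key)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def validate(self, genome: GenomeLayout) -> None:
        for iv in self.intervals:
            if iv.chrom not in genome:
                raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
            if iv.end > genome.length(iv.chrom):
                raise ValueError(
                    f"interval {iv.region_id()} extends past chromosome end "
                    f"{genome.length(iv.chrom)}"
                )

    def total_length(self) -> int:
        """Total bp covered, counting overlapping bases multiply."""
        return sum(iv.width for iv in self.intervals)

    def covered_length(self) -> int:
        """Total bp covered, each base counted once."""
        return merge(self).total_length()

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, sorted by start."""
        out = {}
        for chrom, ivs in self.by_chrom().items():
            out[chrom] = (
                np.array([iv.start for iv in ivs], dtype=np.int64),
                np.array([iv.end for iv in ivs], dtype=np.int64),
            )
        return out


def merge(intervals: IntervalSet, merge_bookended: bool = True) -> IntervalSet:
    """Merge overlapping (and, optionally, touching) intervals.

    The union of covered bases is preserved; names/scores are dropped.
    """
    merged: list[GenomicInterval] = []
    cur: GenomicInterval | None = None
    for iv in intervals:
        if cur is not None and iv.chrom == cur.chrom and (
            iv.start < cur.end or (merge_bookended and iv.start == cur.end)
        ):
            if iv.end > cur.end:
                cur = replace(cur, end=iv.end)
            continue
        if cur is not None:
            merged.append(cur)
        cur = GenomicInterval(iv.chrom, iv.start, iv.end)
    if cur is not None:
        merged.append(cur)
    return IntervalSet(merged)


def intersect_length(a: IntervalSet, b: IntervalSet) -> int:
    """Total number of bases covered by both sets (each base once)."""
    ma, mb = merge(a), merge(b)
    total = 0
    arrays_b = mb.arrays()
    for chrom, (starts_b, ends_b) in arrays_b.items():
        for iv in ma.by_chrom().get(chrom, []):
            lo = np.maximum(starts_b, iv.start)
            hi = np.minimum(ends_b, iv.end)
            total += int(np.clip(hi - lo, 0, None).sum())
    return total


def overlaps_any(regions: IntervalSet, other: IntervalSet, min_overlap_bp: int = 1) -> np.ndarray:
    """Boolean flag per region: does it overlap ``other`` by >= min_overlap_bp?"""
    flags = np.zeros(len(regions), dtype=bool)
    other_arr = merge(other).arrays()
    for i, iv in enumerate(regions):
        if iv.chrom not in other_arr:
            continue
        starts, ends = other_arr[iv.chrom]
        ov = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
        flags[i] = bool((ov >= min_overlap_bp).any())
    return flags


def summit_point(peak: GenomicInterval) -> GenomicInterval:
    """Reduce a peak to its width-1 summit.

    Falls back to the floor midpoint when no summit offset is recorded.
    """
    pos = peak.start + peak.summit if peak.summit is not None else peak.midpoint
    return GenomicInterval(peak.chrom, pos, pos + 1, name=peak.name, score=peak.score)


def distance_to_tss(region: GenomicInterval, tss_chrom: str, tss: int) -> float:
    """Distance in bp from a region to a TSS position.

    0 if the TSS lies inside the region; +inf if on another chromosome.
    """
    if region.chrom != tss_chrom:
        return math.inf
    if region.start <= tss < region.end:
        return 0.0
    return float(min(abs(tss - region.start), abs(tss - (region.end - 1))))


def _eligible_background(
    background: IntervalSet, excluded: IntervalSet
) -> IntervalSet:
    """background minus excluded, as disjoint intervals."""
    bg = merge(background)
    ex = merge(excluded)
    ex_arr = ex.arrays()
    pieces: list[GenomicInterval] = []
    for iv in bg:
        cuts = ex_arr.get(iv.chrom)
        if cuts is None:
            pieces.append(iv)
            continue
        starts, ends = cuts
        pos = iv.start
        sel = (ends > iv.start) & (starts < iv.end)
        for s, e in zip(starts[sel], ends[sel]):
            if s > pos:
                pieces.append(GenomicInterval(iv.chrom, pos, int(s)))
            pos = max(pos, int(e))
        if pos < iv.end:
            pieces.append(GenomicInterval(iv.chrom, pos, iv.end))
    return IntervalSet(pieces)


def _shuffle_starts(
    lengths: np.ndarray,
    bg_starts: np.ndarray,
    bg_ends: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised placement of features into background intervals.

    For each feature length L, an eligible background interval (width >= L)
    is chosen with probability proportional to its number of valid start
    positions (width - L + 1); the start is then uniform within it. Returns
    (chosen interval index, absolute start) per feature.

    Shared by :func:`constrained_shuffle` (one draw) and the bulk
    permutation path in :mod:`enhancerome.tf_enrichment`.
    """
    widths = bg_ends - bg_starts
    n = lengths.shape[0]
    idx = np.empty(n, dtype=np.int64)
    starts = np.empty(n, dtype=np.int64)
    # group features by length so each distinct length costs one weighted draw
    for L in np.unique(lengths):
        mask = lengths == L
        slots = widths - L + 1
        valid = slots > 0
        if not valid.any():
            raise ValueError(
                f"feature of length {int(L)} does not fit in any eligible "
                "background interval"
            )
        weights = np.where(valid, slots, 0).astype(np.float64)
        probs = weights / weights.sum()
        k = int(mask.sum())
        chosen = rng.choice(slots.shape[0], size=k, p=probs)
        offset = rng.integers(0, slots[chosen])  # uniform over valid starts
        idx[mask] = chosen
        starts[mask] = bg_starts[chosen] + offset
    return idx, starts


def constrained_shuffle(
    features: IntervalSet,
    background: IntervalSet,
    excluded: IntervalSet,
    rng_seed: int | np.random.Generator,
) -> IntervalSet:
    """Reposition features uniformly within (background minus excluded).

    The multiset of feature lengths is preserved; every output feature lies
    wholly inside an eligible background interval. Output features may
    overlap one another. Chromosome identity of the original features is not
    preserved — placement is over the whole eligible background.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    eligible = _eligible_background(background, excluded)
    if len(eligible) == 0:
        raise ValueError("background minus excluded is empty")
    bg_chroms = [iv.chrom for iv in eligible]
    bg_starts = np.array([iv.start for iv in eligible], dtype=np.int64)
    bg_ends = np.array([iv.end for iv in eligible], dtype=np.int64)
    lengths = np.array([iv.width for iv in features], dtype=np.int64)
    if lengths.size == 0:
        return IntervalSet([])
    try:
        idx, starts = _shuffle_starts(lengths, bg_starts, bg_ends, rng)
    except ValueError as err:
        # name the offending feature per the error contract
        widths = bg_ends - bg_starts
        for iv in features:
            if iv.width > widths.max():
                raise ValueError(
                    f"feature {iv.region_id()} (length {iv.width}) is longer "
                    "than every eligible background interval"
                ) from err
        raise
    out = [
        GenomicInterval(bg_chroms[i], int(s), int(s + L))
        for i, s, L in zip(idx, starts, lengths)
    ]
    return IntervalSet(out)
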