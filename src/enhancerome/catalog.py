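"""Active-enhancer cataloguing from chromatin-state segmentations.

A per-sample segmentation partitions the genome into 8 labelled states
(promoter, enhancer, elongation, repressed, quiescent flavours). Active
distal enhancers are the merged ActEnh/FlnkActEnh segments, filtered for a
minimum width and for distance from annotated TSSs; the consensus
enhancerome keeps regions seen in a minimum number of samples, and the
conservation matrix records per-sample presence over the 1-sample master
list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, merge, overlaps_any

STATES = (
    "ActTSS",
    "FlnkActTSS",
    "ActEnh",
    "FlnkActEnh",
    "WkEnh",
    "Elong",
    "Repr",
    "Quiescent",
)

ACTIVE_ENHANCER_STATES = ("ActEnh", "FlnkActEnh")
ACTIVE_PROMOTER_STATES = ("ActTSS", "FlnkActTSS")


@dataclass
class StateSegmentation:
    """One sample's genome partition into labelled chromatin states."""

    sample_id: str
    segments: IntervalSet

    def __post_init__(self) -> None:
        for iv in self.segments:
            if iv.name not in STATES:
                raise ValueError(
                    f"unknown state label {iv.name!r} in sample {self.sample_id}"
                )

    def of_states(self, states: tuple[str, ...]) -> IntervalSet:
        return IntervalSet([iv for iv in self.segments if iv.name in states])

    def check_partition(self, genome) -> None:
        """Raise unless segments tile every chromosome without gaps/overlaps."""
        problems = []
        by_chrom = self.segments.by_chrom()
        for chrom, length in genome.chromosomes.items():
            ivs = by_chrom.get(chrom, [])
            pos = 0
            for iv in ivs:
                if iv.start > pos:
                    problems.append(f"{chrom}:{pos}-{iv.start} uncovered")
                elif iv.start < pos:
                    problems.append(f"{chrom}:{iv.start}-{pos} overlapping")
                pos = max(pos, iv.end)
            if pos < length:
                problems.append(f"{chrom}:{pos}-{length} uncovered")
        if problems:
            raise ValueError(
                f"segmentation for {self.sample_id} is not a partition: "
                + "; ".join(problems[:10])
            )


@dataclass
class ConsensusEnhancerSet:
    regions: IntervalSet
    support: np.ndarray  # per-region number of contributing samples
    min_samples: int

    def region_ids(self) -> list[str]:
        return [iv.region_id() for iv in self.regions]


@dataclass
class ConservationMatrix:
    """Binary region x sample presence matrix over the master list."""

    matrix: pd.DataFrame  # index = region ids, columns = sample ids, 0/1
    regions: IntervalSet = field(repr=False)

    @property
    def frequency(self) -> pd.Series:
        return self.matrix.sum(axis=1)


def tss_windows(genes: pd.DataFrame, window: int) -> IntervalSet:
    """±window intervals around each annotated TSS, clipped at 0."""
    ivs = []
    for chrom, tss in zip(genes["chrom"], genes["tss"]):
        start = max(0, int(tss) - window)
        ivs.append(GenomicInterval(str(chrom), start, int(tss) + window + 1))
    return IntervalSet(ivs)


def extract_active_enhancers(
    seg: StateSegmentation,
    genes: pd.DataFrame,
    min_len: int = 200,
    tss_window: int = 5000,
) -> IntervalSet:
    """Merged ActEnh/FlnkActEnh segments, width- and TSS-filtered.

    A merged region is dropped if narrower than ``min_len`` or if it overlaps
    the ±``tss_window`` window around any annotated TSS by >= 1 bp
    (any-overlap rule).
    """
    candidate = merge(seg.of_states(ACTIVE_ENHANCER_STATES))
    wide = IntervalSet([iv for iv in candidate if iv.width >= min_len])
    if len(wide) == 0:
        return wide
    windows = tss_windows(genes, tss_window)
    near_tss = overlaps_any(wide, windows)
    return IntervalSet([iv for iv, hit in zip(wide, near_tss) if not hit])


def build_consensus(
    per_sample: dict[str, IntervalSet], min_samples: int = 2
) -> ConsensusEnhancerSet:
    """Union-merge all per-sample sets; keep regions seen in >= min_samples.

    Support for a merged region = number of samples overlapping it by >=1 bp.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if len(per_sample) < min_samples:
        raise ValueError(
            f"need at least min_samples={min_samples} samples, got {len(per_sample)}"
        )
    pooled = IntervalSet([iv for s in per_sample.values() for iv in s])
    master = merge(pooled)
    support = np.zeros(len(master), dtype=np.int64)
    for sample_set in per_sample.values():
        support += overlaps_any(master, sample_set).astype(np.int64)
    keep = support >= min_samples
    regions = IntervalSet([iv for iv, k in zip(master, keep) if k])
    return ConsensusEnhancerSet(regions, support[keep], min_samples)


def conservation_matrix(
    master: IntervalSet, per_sample: dict[str, IntervalSet]
) -> ConservationMatrix:
    """Presence (1) / absence (0) of each master region per sample."""
    data = {}
    for sample, sample_set in per_sample.items():
        data[sample] = overlaps_any(master, sample_set).astype(np.int64)
    df = pd.DataFrame(data, index=[iv.region_id() for iv in master])
    orphans = df.index[df.sum(axis=1) == 0]
    if len(orphans):
        raise ValueError(
            "master regions overlap no sample (master must be the union-merge "
            f"of the per-sample sets): {list(orphans[:5])}"
        )
    return ConservationMatrix(df, master)


def stratify_by_conservation(
    matrix: ConservationMatrix,
    gained: IntervalSet,
    tiers: tuple[float, ...] = (0.5, 0.8),
) -> dict[float, IntervalSet]:
    """Conservation tiers of gained-overlapping master regions.

    Tier t keeps regions whose carrier frequency is >= ceil(t * n_samples).
    Tiers are nested by construction.
    """
    n_samples = matrix.matrix.shape[1]
    freq = matrix.frequency
    gained_hit = overlaps_any(matrix.regions, gained)
    out: dict[float, IntervalSet] = {}
    for t in tiers:
        threshold = int(np.ceil(t * n_samples))
        keep = [
            iv
            for iv, hit, f in zip(matrix.regions, gained_hit, freq.to_numpy())
            if hit and f >= threshold
        ]
        out[t] = IntervalSet(keep)
    return out
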