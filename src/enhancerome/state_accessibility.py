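"""Conditional probability of open chromatin per chromatin state.

Each accessibility peak is reduced to its 1-bp summit; for every state i,

    p(A|B_i) = (summit bases inside state i) / (total length of state i)

with p(A) = summits / genome length, p(B_i) = state length / genome length,
and p(A ∩ B_i) = summits inside state i / genome length, so that
p(A|B_i) · p(B_i) = p(A ∩ B_i) holds exactly. Summit membership is also
reused to assign whole peaks to the unique state containing their summit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import STATES, StateSegmentation
from .intervals import GenomeLayout, IntervalSet, summit_point


@dataclass
class StateAccessibilityResult:
    table: pd.DataFrame  # index = state; columns p_A, p_B, p_AB, p_A_given_B, n_summits
    genome_length: int


def _summit_positions(peaks: IntervalSet) -> dict[str, np.ndarray]:
    pos: dict[str, list[int]] = {}
    for peak in peaks:
        s = summit_point(peak)
        pos.setdefault(s.chrom, []).append(s.start)
    return {c: np.array(v, dtype=np.int64) for c, v in pos.items()}


def _summits_per_state(
    seg: StateSegmentation, summits: dict[str, np.ndarray], genome: GenomeLayout
) -> dict[str, int]:
    for chrom, positions in summits.items():
        if chrom not in genome or (positions >= genome.length(chrom)).any() or (
            positions < 0
        ).any():
            raise ValueError(f"peak summit outside genome on {chrom}")
    counts = dict.fromkeys(STATES, 0)
    by_chrom = seg.segments.by_chrom()
    for chrom, segments in by_chrom.items():
        positions = summits.get(chrom)
        if positions is None or positions.size == 0:
            continue
        starts = np.array([iv.start for iv in segments])
        ends = np.array([iv.end for iv in segments])
        labels = [iv.name for iv in segments]
        # partition => segments sorted and contiguous; searchsorted locates
        idx = np.searchsorted(starts, positions, side="right") - 1
        for i, p in zip(idx, positions):
            if i < 0 or p >= ends[i]:
                raise ValueError(f"summit {chrom}:{p} falls in a segmentation gap")
            counts[labels[i]] += 1
    return counts


def state_overlap_probability(
    seg: StateSegmentation, peaks: IntervalSet, genome: GenomeLayout
) -> StateAccessibilityResult:
    """Per-state conditional probability of containing a peak summit."""
    seg.check_partition(genome)
    G = genome.total_length
    summits = _summit_positions(peaks)
    n_total = sum(arr.size for arr in summits.values())
    per_state = _summits_per_state(seg, summits, genome)
    state_len = dict.fromkeys(STATES, 0)
    for iv in seg.segments:
        state_len[iv.name] += iv.width
    rows = []
    for state in STATES:
        L = state_len[state]
        k = per_state[state]
        rows.append(
            {
                "state": state,
                "n_summits": k,
                "p_A": n_total / G,
                "p_B": L / G,
                "p_AB": k / G,
                "p_A_given_B": (k / L) if L > 0 else 0.0,
            }
        )
    table = pd.DataFrame(rows).set_index("state")
    return StateAccessibilityResult(table, G)


def peak_state_distribution(
    peaks: IntervalSet, seg: StateSegmentation, genome: GenomeLayout
) -> pd.Series:
    """Fraction of peaks per state; each peak assigned by summit membership."""
    seg.check_partition(genome)
    summits = _summit_positions(peaks)
    counts = _summits_per_state(seg, summits, genome)
    total = sum(counts.values())
    fractions = {s: (counts[s] / total if total else 0.0) for s in STATES}
    return pd.Series(fractions, name="fraction_of_peaks")
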