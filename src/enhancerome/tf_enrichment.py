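"""TF binding of gained-enhancer subsets against a constrained-shuffle null.

The observed statistic is the percentage of subset regions with >= 1 bp
overlap with any TF peak (a region overlapped by several peaks counts
once). The null repositions the subset's features within the enhancerome
background minus the gained regions, preserving the feature-length multiset,
and the one-sided empirical p-value is the fraction of null statistics at
least as large as the observed one — the plain count / n_perm, which can
legitimately be zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import (
    IntervalSet,
    _eligible_background,
    _shuffle_starts,
    merge,
    overlaps_any,
)


@dataclass
class EnrichmentResult:
    subset_name: str
    n_regions: int
    observed_pct: float  # bound fraction, percent
    null_pct: np.ndarray  # length n_perm
    pvalue: float
    rng_seed: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.observed_pct <= 100.0


def bound_fraction(regions: IntervalSet, tf_peaks: IntervalSet) -> float:
    """Percentage of regions overlapping >= 1 TF peak (single-count rule)."""
    if len(regions) == 0:
        raise ValueError("bound_fraction undefined for an empty region set")
    hits = overlaps_any(regions, tf_peaks)
    return 100.0 * float(hits.sum()) / len(regions)


def _null_bound_pct(
    lengths: np.ndarray,
    bg_chrom_codes: np.ndarray,
    bg_starts: np.ndarray,
    bg_ends: np.ndarray,
    peak_starts_by_code: dict[int, tuple[np.ndarray, np.ndarray]],
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised null: n_perm shuffles of all features, bound %% each."""
    n = lengths.size
    all_lengths = np.tile(lengths, n_perm)
    idx, starts = _shuffle_starts(all_lengths, bg_starts, bg_ends, rng)
    ends = starts + all_lengths
    codes = bg_chrom_codes[idx]
    hit = np.zeros(n * n_perm, dtype=bool)
    for code, (p_starts, p_ends) in peak_starts_by_code.items():
        on = codes == code
        if not on.any():
            continue
        s, e = starts[on], ends[on]
        # a feature [s,e) overlaps some merged peak iff the first peak with
        # end > s starts before e
        j = np.searchsorted(p_ends, s, side="right")
        ok = j < p_starts.size
        sub = np.zeros(s.size, dtype=bool)
        sub[ok] = p_starts[j[ok]] < e[ok]
        hit[on] = sub
    return 100.0 * hit.reshape(n_perm, n).mean(axis=1)


def permutation_enrichment(
    subset: IntervalSet,
    tf_peaks: IntervalSet,
    enhancerome: IntervalSet,
    gained: IntervalSet,
    n_perm: int = 1000,
    rng_seed: int = 0,
    subset_name: str = "subset",
    pseudocount: bool = False,
) -> EnrichmentResult:
    """Empirical one-sided enrichment of TF binding in a region subset.

    Null features are placed in (enhancerome minus gained) with probability
    proportional to each eligible interval's count of valid start positions.
    """
    observed = bound_fraction(subset, tf_peaks)
    eligible = _eligible_background(enhancerome, gained)
    if len(eligible) == 0:
        raise ValueError("enhancerome minus gained regions is empty")
    chroms = sorted({iv.chrom for iv in eligible})
    chrom_code = {c: i for i, c in enumerate(chroms)}
    bg_codes = np.array([chrom_code[iv.chrom] for iv in eligible])
    bg_starts = np.array([iv.start for iv in eligible], dtype=np.int64)
    bg_ends = np.array([iv.end for iv in eligible], dtype=np.int64)
    peaks_by_code: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, (p_starts, p_ends) in merge(tf_peaks).arrays().items():
        if chrom in chrom_code:
            peaks_by_code[chrom_code[chrom]] = (p_starts, p_ends)
    lengths = np.array([iv.width for iv in subset], dtype=np.int64)
    rng = np.random.default_rng(rng_seed)
    null = _null_bound_pct(
        lengths, bg_codes, bg_starts, bg_ends, peaks_by_code, n_perm, rng
    )
    n_extreme = int((null >= observed).sum())
    if pseudocount:  # conservative (count+1)/(n_perm+1) variant
        pvalue = (n_extreme + 1) / (n_perm + 1)
    else:
        pvalue = n_extreme / n_perm
    return EnrichmentResult(
        subset_name=subset_name,
        n_regions=len(subset),
        observed_pct=observed,
        null_pct=null,
        pvalue=pvalue,
        rng_seed=rng_seed,
    )
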