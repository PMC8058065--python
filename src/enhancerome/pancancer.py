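"""Pan-cancer accessibility of enhancers across tumor types.

Each enhancer is matched to its best-scoring overlapping accessibility peak;
the resulting enhancer x sample matrix of log2 normalised insertion scores
is collapsed to per-type means, row-clustered (agglomerative, Euclidean
distance, complete linkage), and the high-accessibility cluster is filtered
to rows that exceed the pooled per-type median in *every* type — the
operational reading of "accessible in all cancer types".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .intervals import GenomicInterval, IntervalSet


@dataclass
class AccessibilityMatrix:
    values: pd.DataFrame  # enhancer ids x sample ids, log2 normalised scores
    sample_types: dict[str, str]  # sample -> cancer type

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.sample_types)
        if missing:
            raise ValueError(f"samples without a cancer type: {sorted(missing)}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError(
                "accessibility matrix contains non-finite entries; filter "
                "enhancers without an assigned peak before clustering"
            )

    def per_type_means(self) -> pd.DataFrame:
        types = pd.Series(self.sample_types)
        return self.values.T.groupby(types).mean().T


def assign_best_peak(
    enhancer: GenomicInterval, peaks: IntervalSet
) -> GenomicInterval | None:
    """The highest-scoring peak overlapping the enhancer by >= 1 bp.

    Score ties break to the leftmost peak start; None when no peak overlaps.
    """
    best: GenomicInterval | None = None
    for peak in peaks:
        if peak.chrom != enhancer.chrom:
            continue
        if min(peak.end, enhancer.end) - max(peak.start, enhancer.start) < 1:
            continue
        if peak.score is None:
            raise ValueError(f"peak {peak.region_id()} carries no score")
        if (
            best is None
            or peak.score > best.score
            or (peak.score == best.score and peak.start < best.start)
        ):
            best = peak
    return best


def find_pan_accessible(
    matrix: AccessibilityMatrix,
    n_clusters: int = 2,
    membership_quantile: float = 0.5,
) -> list[str]:
    """Enhancer IDs accessible across all cancer types.

    Per-type mean profiles are clustered (complete linkage, Euclidean);
    within the cluster of highest grand mean, rows must exceed the
    matrix-pooled quantile (default the median over all entries) in every
    type. A single pooled threshold is used because in the colon-like type
    every enhancer is accessible, so a per-type cutoff would sit among the
    high values there and discard genuine pan-accessible rows.
    """
    profiles = matrix.per_type_means()
    if profiles.shape[1] < 2:
        raise ValueError("need >= 2 cancer types")
    X = profiles.to_numpy()
    if X.shape[0] < 2:
        labels = np.ones(X.shape[0], dtype=int)
    else:
        Z = linkage(X, method="complete", metric="euclidean")
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    grand_means = {
        lab: X[labels == lab].mean() for lab in np.unique(labels)
    }
    candidate = max(grand_means, key=grand_means.get)
    threshold = np.quantile(X, membership_quantile)
    in_candidate = labels == candidate
    above_everywhere = (X > threshold).all(axis=1)
    keep = in_candidate & above_everywhere
    if not keep.any():
        warnings.warn(
            "no row exceeds the pooled per-type threshold in every type; "
            "returning an empty pan-accessible set",
            stacklevel=2,
        )
    return list(profiles.index[keep])
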