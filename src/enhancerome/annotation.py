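"""Enhancer-to-gene annotation and gene-set over-representation.

An enhancer overlapping an enhancer-promoter interaction anchor inherits
that anchor's gene(s); otherwise it is assigned the nearest *active*
promoter — the protein-coding gene whose TSS lies in an active-promoter
region — minimising |enhancer midpoint - TSS| on the same chromosome, ties
broken by the lexicographically smallest gene_id. Annotated gene lists are
then tested for over-representation against named gene sets with a
one-sided hypergeometric (Fisher) test, BH-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, IntervalSet, merge


@dataclass
class AnnotationResult:
    table: pd.DataFrame  # enhancer, gene_id, method, distance

    def genes(self) -> list[str]:
        """Deduplicated annotated gene list."""
        return sorted(set(self.table["gene_id"].dropna()))


def eligible_genes(genes: pd.DataFrame, active_promoters: IntervalSet) -> pd.DataFrame:
    """Protein-coding genes whose TSS lies inside an active promoter region."""
    coding = genes[genes["biotype"] == "protein_coding"]
    prom = merge(active_promoters).arrays()
    keep = []
    for _, row in coding.iterrows():
        arr = prom.get(str(row["chrom"]))
        if arr is None:
            keep.append(False)
            continue
        starts, ends = arr
        tss = int(row["tss"])
        i = np.searchsorted(starts, tss, side="right") - 1
        keep.append(bool(i >= 0 and tss < ends[i]))
    return coding[np.array(keep, dtype=bool)] if len(coding) else coding


def annotate(
    enhancers: IntervalSet,
    interactions: pd.DataFrame | None,
    active_promoters: IntervalSet,
    genes: pd.DataFrame,
) -> AnnotationResult:
    """Assign target genes: interaction anchors first, nearest active promoter
    as the fallback. Enhancers with no eligible gene on their chromosome are
    reported unannotated (gene_id = NaN)."""
    elig = eligible_genes(genes, active_promoters)
    elig_by_chrom = {
        chrom: sub.sort_values("gene_id") for chrom, sub in elig.groupby("chrom")
    }
    anchors: dict[str, list[tuple[int, int, str]]] = {}
    if interactions is not None:
        for _, row in interactions.iterrows():
            anchors.setdefault(str(row["chrom"]), []).append(
                (int(row["start"]), int(row["end"]), str(row["gene_id"]))
            )
    rows = []
    for enh in enhancers:
        hit_genes = sorted(
            {
                g
                for (s, e, g) in anchors.get(enh.chrom, [])
                if min(e, enh.end) - max(s, enh.start) >= 1
            }
        )
        if hit_genes:
            for g in hit_genes:
                rows.append(
                    {
                        "enhancer": enh.region_id(),
                        "gene_id": g,
                        "method": "interaction",
                        "distance": 0,
                    }
                )
            continue
        sub = elig_by_chrom.get(enh.chrom)
        if sub is None or len(sub) == 0:
            rows.append(
                {
                    "enhancer": enh.region_id(),
                    "gene_id": np.nan,
                    "method": "unannotated",
                    "distance": np.nan,
                }
            )
            continue
        dists = (sub["tss"].to_numpy(dtype=np.int64) - enh.midpoint)
        dists = np.abs(dists)
        best = dists.min()
        # candidate rows are pre-sorted by gene_id -> first minimum wins ties
        winner = sub.iloc[int(np.argmax(dists == best))]
        rows.append(
            {
                "enhancer": enh.region_id(),
                "gene_id": str(winner["gene_id"]),
                "method": "nearest_active_promoter",
                "distance": int(best),
            }
        )
    return AnnotationResult(pd.DataFrame(rows))


def overrepresentation_test(
    query_genes: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment per gene set, BH across sets.

    Each gene set is intersected with the universe before testing;
    significance is adjusted p < fdr_max (strict, FDR < 5%).
    """
    if not query_genes or not universe:
        raise ValueError("query and universe must be non-empty")
    if not set(query_genes) <= set(universe):
        raise ValueError("query genes must be a subset of the universe")
    N = len(universe)
    n = len(query_genes)
    rows = []
    for name, members in gene_sets.items():
        members_in = set(members) & set(universe)
        K = len(members_in)
        k = len(members_in & set(query_genes))
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"gene_set": name, "set_size": K, "overlap": k, "pvalue": p})
    df = pd.DataFrame(rows)
    _, padj, _, _ = multipletests(df["pvalue"], method="fdr_bh")
    df["padj"] = padj
    df["significant"] = df["padj"] < fdr_max
    return df
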