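"""Differential H3K27ac analysis over consensus enhancer regions.

Counts are normalised by median-of-ratios size factors, then each region is
tested between tumor and normal groups with a two-sided Welch t-test on
log2(normalised count + 1). P-values are Benjamini-Hochberg adjusted across
regions; a region is *gained* at padj <= 0.01 and log2FC >= 2 (tumor over
normal), *lost* at log2FC <= -2. This is a transparent, assumption-light
stand-in for a negative-binomial Wald framework at the identical thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class CountMatrix:
    counts: pd.DataFrame  # regions x samples, non-negative integers
    groups: dict[str, str]  # sample -> "tumor" | "normal"

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]


@dataclass
class DifferentialResult:
    table: pd.DataFrame  # region, log2FC, pvalue, padj, status

    @property
    def gained(self) -> pd.Index:
        return self.table.index[self.table["status"] == "gained"]

    @property
    def lost(self) -> pd.Index:
        return self.table.index[self.table["status"] == "lost"]


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The per-region reference is the geometric mean across samples, computed
    on regions with all-positive counts only.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    x = df.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no region has positive counts in every sample; a pseudo-reference "
            "fallback would be required"
        )
    logx = np.log(x[positive])
    log_geomean = logx.mean(axis=1, keepdims=True)
    log_ratios = logx - log_geomean
    log_factors = np.median(log_ratios, axis=0)
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=df.columns, name="size_factor")


def normalize(counts: CountMatrix) -> pd.DataFrame:
    factors = size_factors(counts)
    return counts.counts / factors


def differential_test(
    counts: CountMatrix, padj_max: float = 0.01, lfc_min: float = 2.0
) -> DifferentialResult:
    """Call gained/lost regions between the tumor and normal groups."""
    tumor = counts.samples_in("tumor")
    normal = counts.samples_in("normal")
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError(
            f"need >=2 samples per group (tumor={len(tumor)}, normal={len(normal)})"
        )
    norm = normalize(counts)
    log_norm = np.log2(norm + 1.0)
    mean_t = norm[tumor].mean(axis=1)
    mean_n = norm[normal].mean(axis=1)
    log2fc = np.log2((mean_t + 1.0) / (mean_n + 1.0))
    tstat, pvalue = stats.ttest_ind(
        log_norm[tumor], log_norm[normal], axis=1, equal_var=False
    )
    pvalue = np.where(np.isnan(pvalue), 1.0, pvalue)
    _, padj, _, _ = multipletests(pvalue, method="fdr_bh")
    status = np.full(len(norm), "unchanged", dtype=object)
    sig = padj <= padj_max
    status[sig & (log2fc.to_numpy() >= lfc_min)] = "gained"
    status[sig & (log2fc.to_numpy() <= -lfc_min)] = "lost"
    table = pd.DataFrame(
        {
            "log2FC": log2fc,
            "pvalue": pvalue,
            "padj": padj,
            "status": status,
        },
        index=norm.index,
    )
    return DifferentialResult(table)
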