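"""Per-cell gene-signature scores (cancer regulatory blueprint / stemness).

For a cell C and gene set G:

    c_score  = fraction of G's genes expressed in C (value > 0)
    e_score  = sum of C's expression over G / sum over all genes
    combined = c_score * e_score
    final    = 1 / (-log(combined))         (natural log by default)

The final transform is monotone in the combined score; combined = 0 maps to
final 0 and combined -> 1 is capped at 1/(-log(1 - cap_epsilon)) to avoid
the singularity. All four quantities are invariant to rescaling a cell's
expression vector by a positive constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SignatureScore:
    geneset_name: str
    table: pd.DataFrame  # per cell: c_score, e_score, combined_score, final


def _check_geneset(matrix: pd.DataFrame, geneset: list[str]) -> list[str]:
    present = [g for g in geneset if g in matrix.columns]
    if not present:
        raise ValueError("gene set has no genes in common with the matrix")
    return present


def coexpression_score(matrix: pd.DataFrame, geneset: list[str]) -> pd.Series:
    """Fraction of gene-set genes expressed (> 0) per cell."""
    present = _check_geneset(matrix, geneset)
    return (matrix[present] > 0).sum(axis=1) / len(present)


def expression_score(matrix: pd.DataFrame, geneset: list[str]) -> pd.Series:
    """Gene-set share of each cell's total expression."""
    present = _check_geneset(matrix, geneset)
    totals = matrix.sum(axis=1)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0][:5])
        raise ValueError(f"cells with zero total expression: {bad}")
    return matrix[present].sum(axis=1) / totals


def transform_combined(
    combined: np.ndarray | pd.Series,
    cap_epsilon: float = 1e-6,
    log_base: float = math.e,
) -> np.ndarray:
    """final = 1 / (-log_b(combined)), with 0 -> 0 and a cap near 1."""
    c = np.asarray(combined, dtype=float)
    cap = 1.0 / (-math.log(1.0 - cap_epsilon) / math.log(log_base))
    out = np.zeros_like(c)
    interior = (c > 0) & (c <= 1.0 - cap_epsilon)
    out[interior] = 1.0 / (-np.log(c[interior]) / math.log(log_base))
    out[c > 1.0 - cap_epsilon] = cap
    return out


def score_all(
    matrix: pd.DataFrame,
    geneset: list[str],
    geneset_name: str = "signature",
    cap_epsilon: float = 1e-6,
    log_base: float = math.e,
) -> SignatureScore:
    """c, e, combined and transformed final score for every cell."""
    c = coexpression_score(matrix, geneset)
    e = expression_score(matrix, geneset)
    combined = c * e
    final = transform_combined(combined.to_numpy(), cap_epsilon, log_base)
    table = pd.DataFrame(
        {
            "c_score": c,
            "e_score": e,
            "combined_score": combined,
            "final": final,
        },
        index=matrix.index,
    )
    return SignatureScore(geneset_name, table)


def score_difference(
    matrix: pd.DataFrame,
    geneset_a: list[str],
    geneset_b: list[str],
    **kwargs,
) -> pd.Series:
    """Per-cell difference of final scores, set A minus set B."""
    a = score_all(matrix, geneset_a, "a", **kwargs)
    b = score_all(matrix, geneset_b, "b", **kwargs)
    return a.table["final"] - b.table["final"]


def population_summary(
    scores: SignatureScore, labels: pd.Series
) -> pd.DataFrame:
    """Median of each score per population label."""
    df = scores.table.copy()
    df["label"] = labels.reindex(df.index)
    return df.groupby("label").median(numeric_only=True)


def compare_populations(
    scores: SignatureScore, labels: pd.Series, group_a: str, group_b: str
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum of final scores between two populations.

    Returns (median difference a-b, p-value).
    """
    final = scores.table["final"]
    lab = labels.reindex(final.index)
    a = final[lab == group_a]
    b = final[lab == group_b]
    stat = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(a.median() - b.median()), float(stat.pvalue)
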