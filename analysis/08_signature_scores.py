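"""Score single cells with the CRB and stemness gene signatures.

Per cell: c_score (fraction of signature genes expressed), e_score
(signature share of total expression), combined = c x e, and the final
1/(-ln combined) transform. Compares malignant against normal epithelial
cells and reports the per-population score medians and their difference.
"""

import pandas as pd

from _cohort import RESULTS, SCRATCH, get_cohort

from enhancerome.scoring import (
    compare_populations,
    population_summary,
    score_all,
    score_difference,
)


def main():
    cohort = get_cohort()
    matrix = cohort.cell_matrix.astype(float)
    matrix = matrix[matrix.sum(axis=1) > 0]  # e_score undefined for empty cells
    crb = score_all(matrix, cohort.truth.signature_genes, "CRB")
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    # per-cell tables are bulky; only the population summaries go to results/
    crb.table.to_csv(SCRATCH / "crb_scores.tsv", sep="\t", index_label="barcode")
    summary = population_summary(crb, cohort.cell_labels)
    summary.to_csv(RESULTS / "crb_population_medians.tsv", sep="\t")
    print("median CRB scores per population:")
    print(summary.to_string(float_format="%.4f"))

    diff, p = compare_populations(
        crb, cohort.cell_labels, "malignant", "normal_epithelial"
    )
    print(f"\nmalignant - normal_epithelial median final score: {diff:.4f} "
          f"(rank-sum p = {p:.3g})")

    delta = score_difference(
        matrix, cohort.truth.signature_genes, cohort.truth.stemness_genes
    )
    delta.name = "crb_minus_stemness"
    delta.to_csv(SCRATCH / "crb_minus_stemness.tsv", sep="\t",
                 index_label="barcode")
    by_pop = delta.groupby(cohort.cell_labels).median()
    by_pop.to_frame().to_csv(RESULTS / "crb_minus_stemness_medians.tsv", sep="\t")
    print("\nmedian CRB - stemness score difference per population:")
    print(by_pop.to_string(float_format="%.4f"))


if __name__ == "__main__":
    main()
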