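"""Find enhancers accessible across all pseudo cancer types.

Clusters the enhancer x sample accessibility panel (per-type means,
complete-linkage hierarchical clustering on Euclidean distances, 2-cluster
cut) and keeps high-cluster rows exceeding the pooled median in every type.
Also demonstrates best-peak assignment for panel enhancers.
"""

import pandas as pd

from _cohort import RESULTS, get_cohort

from enhancerome.intervals import GenomicInterval
from enhancerome.pancancer import assign_best_peak, find_pan_accessible


def main():
    cohort = get_cohort()
    matrix = cohort.accessibility
    pan = find_pan_accessible(matrix)
    RESULTS.mkdir(exist_ok=True)
    pd.Series(sorted(pan), name="region_id").to_csv(
        RESULTS / "pan_accessible_enhancers.tsv", sep="\t", index=False
    )
    truth = cohort.truth.enhancers
    expected = set(truth.loc[truth["pan_accessible"], "region_id"])
    n_panel = len(matrix.values)
    print(f"panel: {n_panel} TAZ-bound gained enhancers across "
          f"{len(set(matrix.sample_types.values()))} cancer types")
    print(f"pan-accessible: {len(pan)} of {n_panel} "
          f"({100 * len(pan) / n_panel:.0f}%)")
    print(f"matches planted truth: {set(pan) == expected}")

    n_assigned = 0
    for rid in matrix.values.index:
        chrom, span = rid.split(":")
        s, e = map(int, span.split("-"))
        if assign_best_peak(GenomicInterval(chrom, s, e), cohort.atac_peaks):
            n_assigned += 1
    print(f"panel enhancers with an assigned best ATAC peak: "
          f"{n_assigned}/{n_panel}")


if __name__ == "__main__":
    main()
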