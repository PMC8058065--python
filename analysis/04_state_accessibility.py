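"""Conditional probability of open chromatin per chromatin state.

Reduces every ATAC peak to its 1-bp summit and computes, per state B_i,
p(A|B_i) = summit bases in state / state length, for each tumor sample;
also the distribution of TF (TAZ) peaks across states for one sample.
"""

import pandas as pd

from _cohort import RESULTS, get_cohort

from enhancerome.state_accessibility import (
    peak_state_distribution,
    state_overlap_probability,
)


def main():
    cohort = get_cohort()
    tables = {}
    for sample, seg in cohort.segmentations.items():
        if not sample.startswith("T"):
            continue
        res = state_overlap_probability(seg, cohort.atac_peaks, cohort.genome)
        tables[sample] = res.table["p_A_given_B"]
    combined = pd.DataFrame(tables)
    RESULTS.mkdir(exist_ok=True)
    combined.to_csv(RESULTS / "state_accessibility.tsv", sep="\t",
                    index_label="state")
    mean = combined.mean(axis=1)
    print("mean p(open | state) across tumor samples:")
    print(mean.sort_values(ascending=False).to_string(float_format="%.2e"))
    top = mean.drop("Quiescent").idxmax()
    fold = mean[top] / mean["Quiescent"] if mean["Quiescent"] > 0 else float("inf")
    print(f"open chromatin concentrates in {top}: "
          f"{fold:.0f}x the quiescent background")

    dist = peak_state_distribution(
        cohort.tf_peaks, cohort.segmentations["T01"], cohort.genome
    )
    dist.to_csv(RESULTS / "taz_peak_state_distribution.tsv", sep="\t",
                index_label="state")
    print("\nTAZ peak distribution across states (sample T01):")
    print(dist[dist > 0].to_string(float_format="%.3f"))


if __name__ == "__main__":
    main()
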