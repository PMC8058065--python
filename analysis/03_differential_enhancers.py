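"""Call gained and lost enhancers from H3K27ac counts.

Median-of-ratios normalisation, Welch test on log2 counts, BH adjustment;
gained/lost at padj <= 0.01 and |log2FC| >= 2. Reports recall of the
planted gained regions and the background call rate.
"""

from _cohort import RESULTS, get_cohort

from enhancerome.differential import differential_test, size_factors


def main():
    cohort = get_cohort()
    res = differential_test(cohort.counts, padj_max=0.01, lfc_min=2.0)
    RESULTS.mkdir(exist_ok=True)
    res.table.to_csv(RESULTS / "differential_enhancers.tsv", sep="\t",
                     index_label="region")
    factors = size_factors(cohort.counts)
    factors.to_csv(RESULTS / "size_factors.tsv", sep="\t", index_label="sample")

    truth = cohort.truth.enhancers.set_index("region_id")
    table = res.table.join(truth["label"], how="left")
    gained_truth = table["label"] == "gained"
    called_gained = table["status"] == "gained"
    recall = (called_gained & gained_truth).sum() / gained_truth.sum()
    background = table["label"] == "background"
    fpr = (called_gained & background).sum() / background.sum()
    print(f"{called_gained.sum()} gained, {(table['status'] == 'lost').sum()} lost "
          f"of {len(table)} consensus regions")
    print(f"recall of planted gained regions: {100 * recall:.1f}% "
          f"(planted carriers vary from 2 to 10 of 10 tumors; low-conservation "
          f"regions dilute the group mean and can stay below |log2FC| >= 2)")
    print(f"background regions called gained: {100 * fpr:.2f}%")


if __name__ == "__main__":
    main()
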