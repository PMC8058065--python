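"""Simulate the synthetic study cohort and write it to disk.

Generates the full bundle — genome, gene annotation, 15 chromatin-state
segmentations (10 tumor, 5 normal) with planted gained/lost enhancers,
H3K27ac counts, TF and ATAC peak sets, the pan-cancer accessibility panel,
enhancer-promoter interactions, and a labelled single-cell matrix — then
writes the fixture under scratch/cohort and a design summary under results/.
"""

from _cohort import ANALYSIS_SEED, RESULTS, SCRATCH

import pandas as pd

from enhancerome.synthetic import CohortConfig, simulate_cohort, write_fixture


def main():
    config = CohortConfig(rng_seed=ANALYSIS_SEED)
    bundle = simulate_cohort(config)
    write_fixture(bundle, SCRATCH)
    truth = bundle.truth.enhancers
    summary = truth["label"].value_counts().rename_axis("label").to_frame("n")
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "cohort_summary.tsv", sep="\t")
    print(f"cohort written to {SCRATCH}")
    print(f"genome: {len(bundle.genome.chromosomes)} chromosomes, "
          f"{bundle.genome.total_length / 1e6:.1f} Mb")
    print(f"samples: {sum(g == 'tumor' for g in bundle.counts.groups.values())} tumor, "
          f"{sum(g == 'normal' for g in bundle.counts.groups.values())} normal")
    print("planted regions:")
    print(summary.to_string())
    print(f"cells: {bundle.cell_matrix.shape[0]} x {bundle.cell_matrix.shape[1]} genes; "
          f"signature of {len(bundle.truth.signature_genes)} genes")


if __name__ == "__main__":
    main()
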