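"""Enhancer extraction, consensus building, conservation, tier stratification."""

import numpy as np
import pandas as pd
import pytest

from enhancerome.catalog import (
    ConservationMatrix,
    StateSegmentation,
    build_consensus,
    conservation_matrix,
    extract_active_enhancers,
    stratify_by_conservation,
)
from enhancerome.intervals import GenomeLayout, GenomicInterval, IntervalSet


def seg_from(sample, triples):
    return StateSegmentation(
        sample, IntervalSet([GenomicInterval(c, s, e, name=st) for c, s, e, st in triples])
    )


def genes_at(*positions):
    return pd.DataFrame(
        {
            "gene_id": [f"G{i}" for i in range(len(positions))],
            "chrom": ["chr1"] * len(positions),
            "tss": list(positions),
            "strand": ["+"] * len(positions),
            "biotype": ["protein_coding"] * len(positions),
        }
    )


FAR_GENE = genes_at(900_000)


class TestExtractActiveEnhancers:
    def test_no_enhancer_states_gives_empty(self):
        seg = seg_from("s", [("chr1", 0, 1000, "Quiescent")])
        assert len(extract_active_enhancers(seg, FAR_GENE)) == 0

    def test_length_filter_drops_short_region(self):
        seg = seg_from("s", [("chr1", 10_000, 10_150, "ActEnh")])
        assert len(extract_active_enhancers(seg, FAR_GENE)) == 0

    def test_adjacent_states_merge_before_length_filter(self):
        seg = seg_from(
            "s",
            [
                ("chr1", 10_000, 10_150, "ActEnh"),
                ("chr1", 10_150, 10_300, "FlnkActEnh"),
            ],
        )
        got = extract_active_enhancers(seg, FAR_GENE)
        assert [(iv.start, iv.end) for iv in got] == [(10_000, 10_300)]

    @pytest.mark.parametrize(
        "tss_distance,kept",
        [(4_900, False), (5_100, True)],
    )
    def test_tss_window_filter(self, tss_distance, kept):
        # 300 bp region whose nearest edge is tss_distance from the TSS
        start = 50_000
        seg = seg_from("s", [("chr1", start, start + 300, "ActEnh")])
        genes = genes_at(start - tss_distance)
        got = extract_active_enhancers(seg, genes, tss_window=5000)
        assert (len(got) == 1) == kept

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError, match="unknown state"):
            seg_from("s", [("chr1", 0, 100, "Enhancer")])


class TestBuildConsensus:
    def test_region_in_single_sample_dropped(self):
        per = {
            "A": IntervalSet([GenomicInterval("chr1", 0, 500)]),
            **{s: IntervalSet([]) for s in "BCDEFGHIJKLMNO"},
        }
        cons = build_consensus(per, min_samples=2)
        assert len(cons.regions) == 0

    def test_overlapping_regions_merge_with_support(self):
        per = {
            "A": IntervalSet([GenomicInterval("chr1", 0, 500)]),
            "B": IntervalSet([GenomicInterval("chr1", 400, 900)]),
            "C": IntervalSet([GenomicInterval("chr1", 100, 600)]),
        }
        cons = build_consensus(per, min_samples=2)
        assert [(iv.start, iv.end) for iv in cons.regions] == [(0, 900)]
        assert list(cons.support) == [3]

    def test_identical_sets_support_equals_n_samples(self):
        base = IntervalSet([GenomicInterval("chr1", 100, 300), GenomicInterval("chr2", 0, 200)])
        per = {f"s{i}": base for i in range(5)}
        cons = build_consensus(per, min_samples=2)
        assert cons.regions == IntervalSet(
            [GenomicInterval("chr1", 100, 300), GenomicInterval("chr2", 0, 200)]
        )
        assert (cons.support == 5).all()

    def test_min_samples_below_one_rejected(self):
        with pytest.raises(ValueError, match="min_samples"):
            build_consensus({"A": IntervalSet([])}, min_samples=0)


class TestConservationMatrix:
    def test_single_sample_frequencies_all_one(self):
        master = IntervalSet([GenomicInterval("chr1", 0, 100)])
        cm = conservation_matrix(master, {"A": master})
        assert (cm.frequency == 1).all()

    def test_presence_pattern(self):
        master = IntervalSet([GenomicInterval("chr1", 0, 100)])
        per = {
            "s1": IntervalSet([GenomicInterval("chr1", 50, 80)]),
            "s2": IntervalSet([GenomicInterval("chr2", 0, 100)]),
            "s3": IntervalSet([GenomicInterval("chr1", 99, 200)]),
        }
        cm = conservation_matrix(master, per)
        assert list(cm.matrix.iloc[0]) == [1, 0, 1]
        assert cm.frequency.iloc[0] == 2

    def test_orphan_master_region_rejected(self):
        master = IntervalSet([GenomicInterval("chr1", 0, 100)])
        with pytest.raises(ValueError, match="master"):
            conservation_matrix(master, {"A": IntervalSet([])})


class TestStratifyByConservation:
    @pytest.fixture()
    def setup(self):
        regions = IntervalSet(
            [GenomicInterval("chr1", i * 1000, i * 1000 + 500) for i in range(3)]
        )
        freqs = [8, 5, 4]  # of 10 tumor samples
        data = {
            f"T{s}": [1 if s < f else 0 for f in freqs] for s in range(10)
        }
        matrix = ConservationMatrix(
            pd.DataFrame(data, index=[iv.region_id() for iv in regions]), regions
        )
        return matrix, regions

    def test_tier_thresholds(self, setup):
        matrix, regions = setup
        gained = regions  # all overlap a gained region
        tiers = stratify_by_conservation(matrix, gained)
        ids = {t: {iv.region_id() for iv in s} for t, s in tiers.items()}
        assert ids[0.5] == {"chr1:0-500", "chr1:1000-1500"}  # freq 8 and 5
        assert ids[0.8] == {"chr1:0-500"}  # freq 8 only

    def test_tiers_nested_and_empty_gained(self, setup):
        matrix, regions = setup
        tiers = stratify_by_conservation(matrix, IntervalSet([]))
        assert all(len(s) == 0 for s in tiers.values())
        tiers = stratify_by_conservation(matrix, regions)
        ids8 = {iv.region_id() for iv in tiers[0.8]}
        ids5 = {iv.region_id() for iv in tiers[0.5]}
        assert ids8 <= ids5


def test_pipeline_recovers_planted_enhancers(cohort):
    """>= 95% of >= 2-carrier planted enhancers recovered; no decoys."""
    per_sample = {
        s: extract_active_enhancers(seg, cohort.genes)
        for s, seg in cohort.segmentations.items()
    }
    cons = build_consensus(per_sample, min_samples=2)
    found = set(rid for rid in (iv.region_id() for iv in cons.regions))
    truth = cohort.truth.enhancers
    eligible = truth[
        truth["label"].isin(["gained", "lost", "background"])
    ]["region_id"]
    recovered = sum(rid in found for rid in eligible) / len(eligible)
    assert recovered >= 0.95
    decoys = truth.loc[truth["label"] == "decoy", "region_id"]
    assert not any(rid in found for rid in decoys)
    singletons = truth.loc[truth["label"] == "singleton", "region_id"]
    assert not any(rid in found for rid in singletons)
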