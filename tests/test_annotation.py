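"""Enhancer-to-gene annotation and over-representation testing."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from enhancerome.annotation import annotate, overrepresentation_test
from enhancerome.intervals import GenomicInterval, IntervalSet


def gene_table(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "tss", "strand", "biotype"]
    )


PROMOTERS = IntervalSet([GenomicInterval("chr1", 0, 1_000_000)])  # everything active


class TestAnnotate:
    def test_interaction_takes_precedence(self):
        genes = gene_table([("geneX", "chr1", 500, "+", "protein_coding"),
                            ("geneY", "chr1", 900, "+", "protein_coding")])
        enh = IntervalSet([GenomicInterval("chr1", 10_000, 11_000)])
        inter = pd.DataFrame(
            [{"chrom": "chr1", "start": 10_500, "end": 10_600, "gene_id": "geneX"}]
        )
        res = annotate(enh, inter, PROMOTERS, genes)
        assert list(res.table["gene_id"]) == ["geneX"]
        assert list(res.table["method"]) == ["interaction"]
        assert list(res.table["distance"]) == [0]

    def test_nearest_active_promoter_by_midpoint(self):
        # midpoint 10_500; TSSs at 12_000 and 30_000 bp away
        genes = gene_table(
            [
                ("far", "chr1", 40_500, "+", "protein_coding"),
                ("near", "chr1", 22_500, "+", "protein_coding"),
            ]
        )
        enh = IntervalSet([GenomicInterval("chr1", 10_000, 11_000)])
        res = annotate(enh, None, PROMOTERS, genes)
        assert list(res.table["gene_id"]) == ["near"]
        assert list(res.table["method"]) == ["nearest_active_promoter"]
        assert list(res.table["distance"]) == [12_000]

    def test_equidistant_tie_breaks_to_smallest_gene_id(self):
        genes = gene_table(
            [
                ("GACT", "chr1", 9_000, "+", "protein_coding"),
                ("GAAA", "chr1", 12_000, "+", "protein_coding"),
            ]
        )
        enh = IntervalSet([GenomicInterval("chr1", 10_000, 11_000)])  # midpoint 10_500
        res = annotate(enh, None, PROMOTERS, genes)
        assert list(res.table["gene_id"]) == ["GAAA"]

    def test_non_coding_and_inactive_genes_ineligible(self):
        promoters = IntervalSet([GenomicInterval("chr1", 0, 5_000)])
        genes = gene_table(
            [
                ("linc", "chr1", 10_400, "+", "lincRNA"),  # wrong biotype
                ("off", "chr1", 50_000, "+", "protein_coding"),  # TSS not active
                ("ok", "chr1", 1_000, "+", "protein_coding"),
            ]
        )
        enh = IntervalSet([GenomicInterval("chr1", 10_000, 11_000)])
        res = annotate(enh, None, promoters, genes)
        assert list(res.table["gene_id"]) == ["ok"]

    def test_unannotated_when_no_eligible_gene_on_chromosome(self):
        genes = gene_table([("g", "chr2", 100, "+", "protein_coding")])
        enh = IntervalSet([GenomicInterval("chr1", 10_000, 11_000)])
        res = annotate(enh, None, PROMOTERS, genes)
        assert list(res.table["method"]) == ["unannotated"]
        assert res.table["gene_id"].isna().all()

    def test_removing_interactions_switches_exactly_those_methods(self):
        rng = np.random.default_rng(1)
        genes = gene_table(
            [(f"G{i:03d}", "chr1", 1_000 + 10_000 * i, "+", "protein_coding") for i in range(20)]
        )
        enh = IntervalSet(
            [GenomicInterval("chr1", int(s), int(s) + 500) for s in rng.integers(0, 190_000, 30)]
        )
        inter = pd.DataFrame(
            [
                {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "gene_id": "G000"}
                for iv in list(enh)[:10]
            ]
        )
        with_map = annotate(enh, inter, PROMOTERS, genes)
        without = annotate(enh, None, PROMOTERS, genes)
        was_inter = set(
            with_map.table.loc[with_map.table["method"] == "interaction", "enhancer"]
        )
        for enh_id in set(without.table["enhancer"]):
            m = without.table.loc[without.table["enhancer"] == enh_id, "method"].iloc[0]
            assert m != "interaction"
            if enh_id in was_inter:
                assert m == "nearest_active_promoter"

    def test_nearest_assignment_matches_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n_genes = int(rng.integers(1, 8))
            genes = gene_table(
                [
                    (f"G{i}", "chr1", int(rng.integers(0, 100_000)), "+", "protein_coding")
                    for i in range(n_genes)
                ]
            )
            s = int(rng.integers(0, 99_000))
            enh = IntervalSet([GenomicInterval("chr1", s, s + int(rng.integers(1, 1000)))])
            res = annotate(enh, None, PROMOTERS, genes)
            mid = enh[0].midpoint
            best = min(
                genes.itertuples(), key=lambda g: (abs(g.tss - mid), g.gene_id)
            )
            assert res.table["gene_id"].iloc[0] == best.gene_id


class TestOverrepresentation:
    def test_exact_hypergeometric_example(self):
        universe = {f"g{i}" for i in range(20)}
        geneset = {f"g{i}" for i in range(5)}
        query = {"g0", "g1", "g2", "g3", "g19"}  # 4 hits
        res = overrepresentation_test(query, {"set": geneset}, universe)
        expected = sum(
            comb(5, k) * comb(15, 5 - k) for k in range(4, 6)
        ) / comb(20, 5)
        assert res["pvalue"].iloc[0] == pytest.approx(expected, rel=1e-9)
        assert res["pvalue"].iloc[0] == pytest.approx(0.004902, abs=5e-7)

    def test_disjoint_query_gives_p_one(self):
        universe = {f"g{i}" for i in range(30)}
        sets = {"a": {"g0", "g1"}, "b": {"g2", "g3", "g4"}}
        query = {"g10", "g11"}
        res = overrepresentation_test(query, sets, universe)
        assert (res["pvalue"] == 1.0).all()

    def test_query_equal_to_set_attains_minimum_p(self):
        universe = {f"g{i}" for i in range(30)}
        target = {"g0", "g1", "g2", "g3"}
        res_full = overrepresentation_test(target, {"t": target}, universe)
        # any smaller overlap with the same sizes gives a larger p
        res_partial = overrepresentation_test(
            {"g0", "g1", "g2", "g10"}, {"t": target}, universe
        )
        assert res_full["pvalue"].iloc[0] < res_partial["pvalue"].iloc[0]

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            overrepresentation_test(set(), {"a": {"g"}}, {"g"})

    def test_fdr_flag_is_strict(self):
        universe = {f"g{i}" for i in range(100)}
        sets = {"hit": {f"g{i}" for i in range(10)}, "miss": {f"g{i}" for i in range(90, 95)}}
        query = {f"g{i}" for i in range(10)}
        res = overrepresentation_test(query, sets, universe).set_index("gene_set")
        assert bool(res.loc["hit", "significant"])
        assert not bool(res.loc["miss", "significant"])


def test_cohort_gained_genes_enrich_for_signature(cohort):
    """Genes annotated to gained enhancers over-represent the planted
    signature set relative to the whole annotation."""
    from enhancerome.catalog import ACTIVE_PROMOTER_STATES
    from enhancerome.intervals import merge

    promoters = merge(
        IntervalSet(
            [
                iv
                for seg in cohort.segmentations.values()
                for iv in seg.of_states(ACTIVE_PROMOTER_STATES)
            ]
        )
    )
    gained = cohort.truth.of_label("gained")
    res = annotate(gained, cohort.interactions, promoters, cohort.genes)
    query = set(res.genes())
    universe = set(cohort.genes["gene_id"])
    sets = {
        "signature": set(cohort.truth.signature_genes),
        "stemness": set(cohort.truth.stemness_genes),
    }
    table = overrepresentation_test(query & universe, sets, universe).set_index("gene_set")
    assert table.loc["signature", "pvalue"] < table.loc["stemness", "pvalue"]
    assert bool(table.loc["signature", "significant"])
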