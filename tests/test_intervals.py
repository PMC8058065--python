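"""Interval-engine semantics: merge, overlap, summits, distances, shuffling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enhancerome.intervals import (
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    constrained_shuffle,
    distance_to_tss,
    intersect_length,
    merge,
    summit_point,
)
from .conftest import random_interval_set


def covered_bases(ivs: IntervalSet) -> set[tuple[str, int]]:
    """Brute-force base-set oracle."""
    return {(iv.chrom, p) for iv in ivs for p in range(iv.start, iv.end)}


intervals_strategy = st.lists(
    st.tuples(
        st.sampled_from(["chr1", "chr2"]),
        st.integers(0, 200),
        st.integers(1, 60),
    ).map(lambda t: GenomicInterval(t[0], t[1], t[1] + t[2])),
    max_size=15,
)


class TestMerge:
    def test_empty(self):
        assert len(merge(IntervalSet([]))) == 0

    @pytest.mark.parametrize(
        "raw,bookended,expected",
        [
            ([(0, 10), (5, 20)], True, [(0, 20)]),
            ([(0, 10), (10, 20)], True, [(0, 20)]),
            ([(0, 10), (10, 20)], False, [(0, 10), (10, 20)]),
            ([(0, 10), (11, 20)], True, [(0, 10), (11, 20)]),
        ],
    )
    def test_examples(self, raw, bookended, expected):
        got = merge(
            IntervalSet([GenomicInterval("chr1", s, e) for s, e in raw]),
            merge_bookended=bookended,
        )
        assert [(iv.start, iv.end) for iv in got] == expected

    @given(intervals_strategy)
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_union_preserved_and_idempotent(self, ivs):
        s = IntervalSet(ivs)
        m = merge(s)
        assert covered_bases(m) == covered_bases(s)
        assert merge(m) == m
        # disjointness
        for a, b in zip(m.intervals, m.intervals[1:]):
            assert a.chrom != b.chrom or a.end < b.start

    def test_unknown_chromosome_error(self, toy_genome):
        s = IntervalSet([GenomicInterval("chrX", 0, 10)])
        with pytest.raises(ValueError, match="chrX"):
            s.validate(toy_genome)


class TestIntersectLength:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([("chr1", 0, 10)], [("chr1", 5, 15)], 5),
            ([("chr1", 0, 10)], [("chr2", 0, 10)], 0),
            ([("chr1", 0, 100)], [("chr1", 0, 100)], 100),
        ],
    )
    def test_examples(self, a, b, expected):
        A = IntervalSet([GenomicInterval(*t) for t in a])
        B = IntervalSet([GenomicInterval(*t) for t in b])
        assert intersect_length(A, B) == expected
        assert intersect_length(B, A) == expected

    def test_matches_per_base_oracle_on_random_sets(self, toy_genome):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a = random_interval_set(rng, toy_genome, int(rng.integers(0, 12)))
            b = random_interval_set(rng, toy_genome, int(rng.integers(0, 12)))
            expected = len(covered_bases(a) & covered_bases(b))
            assert intersect_length(a, b) == expected


class TestSummitPoint:
    @pytest.mark.parametrize(
        "start,end,summit,expected",
        [
            (100, 200, 30, 130),
            (100, 200, None, 150),
            (7, 8, None, 7),
        ],
    )
    def test_examples(self, start, end, summit, expected):
        s = summit_point(GenomicInterval("chr1", start, end, summit=summit))
        assert (s.start, s.end) == (expected, expected + 1)


class TestDistanceToTss:
    @pytest.mark.parametrize(
        "tss,expected",
        [(1100, 0.0), (1500, 301.0), (400, 600.0)],
    )
    def test_examples(self, tss, expected):
        region = GenomicInterval("chr1", 1000, 1200)
        assert distance_to_tss(region, "chr1", tss) == expected

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            s = int(rng.integers(0, 500))
            e = s + int(rng.integers(1, 100))
            tss = int(rng.integers(0, 700))
            region = GenomicInterval("chr1", s, e)
            expected = float(min(abs(tss - p) for p in range(s, e)))
            assert distance_to_tss(region, "chr1", tss) == expected

    def test_other_chromosome_is_infinite(self):
        assert math.isinf(
            distance_to_tss(GenomicInterval("chr1", 0, 10), "chr2", 5)
        )


class TestConstrainedShuffle:
    def test_unique_placement(self):
        feat = IntervalSet([GenomicInterval("chr1", 500, 600)])
        bg = IntervalSet([GenomicInterval("chr1", 1000, 1100)])
        out = constrained_shuffle(feat, bg, IntervalSet([]), rng_seed=0)
        assert [(iv.start, iv.end) for iv in out] == [(1000, 1100)]

    def test_length_multiset_and_exclusion_and_containment(self):
        rng = np.random.default_rng(3)
        genome = GenomeLayout({"chr1": 100_000})
        bg = IntervalSet(
            [GenomicInterval("chr1", i * 1000, i * 1000 + 800) for i in range(100)]
        )
        excluded = IntervalSet(
            [GenomicInterval("chr1", i * 1000, i * 1000 + 800) for i in range(0, 100, 5)]
        )
        feats = IntervalSet(
            [
                GenomicInterval("chr1", 0, int(rng.integers(50, 700)))
                for _ in range(30)
            ]
        )
        out = constrained_shuffle(feats, bg, excluded, rng_seed=9)
        assert sorted(iv.width for iv in out) == sorted(iv.width for iv in feats)
        assert intersect_length(out, excluded) == 0
        for iv in out:
            assert intersect_length(IntervalSet([iv]), bg) == iv.width

    def test_seed_reproducibility(self):
        feats = IntervalSet([GenomicInterval("chr1", 0, 100) for _ in range(10)])
        bg = IntervalSet([GenomicInterval("chr1", 0, 50_000)])
        a = constrained_shuffle(feats, bg, IntervalSet([]), rng_seed=5)
        b = constrained_shuffle(feats, bg, IntervalSet([]), rng_seed=5)
        assert a == b

    def test_placement_probability_two_intervals(self):
        # 10 vs 100 valid starts -> P(first) = 10/110
        feat = IntervalSet([GenomicInterval("chr1", 0, 10)])
        bg = IntervalSet(
            [GenomicInterval("chr1", 0, 19), GenomicInterval("chr1", 1000, 1109)]
        )
        rng = np.random.default_rng(2024)
        hits = 0
        n = 10_000
        for _ in range(n):
            out = constrained_shuffle(feat, bg, IntervalSet([]), rng)
            hits += out[0].end <= 19
        assert abs(hits / n - 10 / 110) < 0.01

    def test_oversized_feature_error(self):
        feat = IntervalSet([GenomicInterval("chr1", 0, 500)])
        bg = IntervalSet([GenomicInterval("chr1", 0, 100)])
        with pytest.raises(ValueError, match="chr1:0-500"):
            constrained_shuffle(feat, bg, IntervalSet([]), rng_seed=0)


def test_merge_agrees_with_bedtools(tmp_path):
    """Independent cross-check of merge/intersect against bedtools."""
    import shutil
    import subprocess

    if shutil.which("bedtools") is None:
        pytest.skip("bedtools not on PATH")
    rng = np.random.default_rng(123)
    genome = GenomeLayout({"chr1": 50_000, "chr2": 30_000})
    s = random_interval_set(rng, genome, 40, max_len=2000)
    bed = tmp_path / "in.bed"
    bed.write_text("".join(f"{iv.chrom}\t{iv.start}\t{iv.end}\n" for iv in s))
    out = subprocess.run(
        ["bedtools", "merge", "-i", str(bed)], capture_output=True, text=True,
        check=True,
    )
    expected = [
        (f[0], int(f[1]), int(f[2]))
        for f in (line.split("\t") for line in out.stdout.strip().split("\n"))
    ]
    got = [(iv.chrom, iv.start, iv.end) for iv in merge(s)]
    assert got == sorted(expected)
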