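"""Interval algebra: examples, brute-force-oracle agreement, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tadlink import (
    DISTANCE_BINS,
    GenomicInterval,
    IntervalSet,
    NoReferenceError,
    assign_to_domain,
    classify_distance,
    distance_to_nearest_tss,
    intersect_keep,
    merge,
    subtract_drop,
    validate_non_overlapping,
)
from tadlink.io import GeneModel

from _oracles import (
    covered_bases_oracle,
    intersect_keep_mask_oracle,
    intersect_keep_oracle,
    nearest_tss_oracle,
    random_interval_set,
)


def iset(*triples):
    return IntervalSet(GenomicInterval(c, s, e) for c, s, e in triples)


class TestGenomicInterval:
    def test_rejects_empty_and_inverted(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 100)

    def test_length_and_midpoint(self):
        iv = GenomicInterval("chr1", 100, 201)
        assert iv.length == 101
        assert iv.midpoint == 150


class TestIntersectKeep:
    def test_basic_overlap_keeps_original_coordinates(self):
        out = intersect_keep(iset(("chr1", 100, 200)), iset(("chr1", 150, 300)), 1)
        assert list(out) == [GenomicInterval("chr1", 100, 200)]

    def test_half_open_adjacency_is_not_overlap(self):
        out = intersect_keep(iset(("chr1", 100, 200)), iset(("chr1", 200, 300)), 1)
        assert len(out) == 0

    def test_min_overlap_threshold(self):
        a, b = iset(("chr1", 100, 200)), iset(("chr1", 190, 300))
        assert len(intersect_keep(a, b, 10)) == 1
        assert len(intersect_keep(a, b, 11)) == 0

    def test_overlap_is_per_element_not_pooled(self):
        # two abutting b elements each give 10 bp; they may not pool to 20
        a = iset(("chr1", 100, 200))
        b = iset(("chr1", 140, 150), ("chr1", 150, 160))
        assert len(intersect_keep(a, b, 15)) == 0
        assert len(intersect_keep(a, b, 10)) == 1

    def test_invalid_min_overlap(self):
        with pytest.raises(ValueError):
            intersect_keep(iset(), iset(), 0)

    def test_idempotent(self, rng):
        a = random_interval_set(rng, 50, 100_000)
        b = random_interval_set(rng, 50, 100_000)
        once = intersect_keep(a, b, 5)
        assert intersect_keep(once, b, 5) == once

    def test_agrees_with_per_base_oracle(self, rng):
        for _ in range(60):
            L = int(rng.integers(1_000, 1_000_000))
            a = random_interval_set(rng, int(rng.integers(1, 200)), L, ("c1", "c2"))
            b = random_interval_set(rng, int(rng.integers(1, 200)), L, ("c1", "c2"))
            assert intersect_keep(a, b, 1) == intersect_keep_mask_oracle(a, b, L)
            m = int(rng.integers(1, 50))
            assert intersect_keep(a, b, m) == intersect_keep_oracle(a, b, m, L)

    def test_agrees_with_pyranges(self, rng):
        pr = pytest.importorskip("pyranges")
        import pandas as pd

        a = random_interval_set(rng, 150, 500_000, ("c1", "c2"))
        b = random_interval_set(rng, 150, 500_000, ("c1", "c2"))

        def to_pr(s):
            return pr.PyRanges(
                pd.DataFrame(
                    {
                        "Chromosome": [iv.chrom for iv in s],
                        "Start": [iv.start for iv in s],
                        "End": [iv.end for iv in s],
                    }
                )
            )

        got = {(iv.chrom, iv.start, iv.end) for iv in intersect_keep(a, b, 1)}
        df = to_pr(a).overlap(to_pr(b)).df
        want = set(df.itertuples(index=False, name=None)) if len(df) else set()
        assert got == want


class TestSubtractDrop:
    def test_empty_subtrahend_is_identity(self):
        a = iset(("chr1", 100, 200))
        assert subtract_drop(a, iset()) == a

    def test_any_overlap_removes_whole_element(self):
        out = subtract_drop(iset(("chr1", 100, 200)), iset(("chr1", 150, 160)))
        assert len(out) == 0

    def test_equals_set_difference_oracle(self, rng):
        a = random_interval_set(rng, 100, 200_000)
        b = random_interval_set(rng, 100, 200_000)
        kept_ids = {(iv.chrom, iv.start, iv.end) for iv in intersect_keep(a, b, 1)}
        expected = IntervalSet(
            iv for iv in a if (iv.chrom, iv.start, iv.end) not in kept_ids
        )
        assert subtract_drop(a, b) == expected

    def test_partition_property(self, rng):
        for _ in range(30):
            L = int(rng.integers(1_000, 1_000_000))
            a = random_interval_set(rng, int(rng.integers(1, 150)), L)
            b = random_interval_set(rng, int(rng.integers(1, 150)), L)
            assert len(a) == len(intersect_keep(a, b, 1)) + len(subtract_drop(a, b))


class TestMerge:
    def test_overlapping_union(self):
        assert merge(iset(("chr1", 0, 10), ("chr1", 5, 20)), 0) == iset(("chr1", 0, 20))

    def test_one_bp_gap_preserved_at_gap_zero(self):
        a = iset(("chr1", 0, 10), ("chr1", 11, 20))
        assert merge(a, 0) == a

    def test_gap_bridging(self):
        a = iset(("chr1", 0, 10), ("chr1", 11, 20))
        assert merge(a, 1) == iset(("chr1", 0, 20))

    def test_idempotent_and_conserves_coverage(self, rng):
        for _ in range(30):
            L = int(rng.integers(1_000, 1_000_000))
            a = random_interval_set(rng, int(rng.integers(1, 150)), L, ("c1", "c2"))
            m = merge(a, 0)
            assert merge(m, 0) == m
            # non-overlapping output
            validate_non_overlapping(m)
            assert covered_bases_oracle(m, ("c1", "c2"), L) == covered_bases_oracle(
                a, ("c1", "c2"), L
            )


class TestDistanceToNearestTss:
    def test_tss_at_center_is_zero(self):
        g = GeneModel("g1", "chr1", "+", [1000])
        assert distance_to_nearest_tss(GenomicInterval("chr1", 990, 1010), [g]) == 0

    def test_center_anchor_arithmetic(self):
        g = GeneModel("g1", "chr1", "+", [8000])
        assert distance_to_nearest_tss(GenomicInterval("chr1", 0, 1000), [g]) == 7500

    def test_no_gene_on_chromosome_raises(self):
        g = GeneModel("g1", "chr2", "+", [100])
        with pytest.raises(NoReferenceError):
            distance_to_nearest_tss(GenomicInterval("chr1", 0, 10), [g])

    def test_agrees_with_all_pairs_oracle(self, rng):
        genes = [
            GeneModel(f"g{i}", "c1", "+", sorted(set(rng.integers(0, 1_000_000, 2).tolist())) or [0])
            for i in range(50)
        ]
        peaks = random_interval_set(rng, 500, 1_000_000)
        for p in peaks:
            assert distance_to_nearest_tss(p, genes) == nearest_tss_oracle(p, genes)


class TestClassifyDistance:
    @pytest.mark.parametrize(
        "d,label",
        [
            (0, "0-5 kb"),
            (4_999, "0-5 kb"),
            (5_000, "5-50 kb"),
            (49_999, "5-50 kb"),
            (50_000, "50-500 kb"),
            (500_000, ">500 kb"),
            (10**9, ">500 kb"),
        ],
    )
    def test_half_open_bins_with_inclusive_lower_edges(self, d, label):
        assert classify_distance(d) == label

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            classify_distance(-1)

    @settings(max_examples=300, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**8))
    def test_every_distance_in_exactly_one_bin(self, d):
        assert sum(b.contains(d) for b in DISTANCE_BINS) == 1


class TestAssignToDomain:
    def test_midpoint_containment(self):
        tads = iset(("chr1", 0, 1000))
        assert assign_to_domain(GenomicInterval("chr1", 100, 200), tads) == 0

    def test_boundary_straddling_follows_midpoint(self):
        tads = iset(("chr1", 0, 1000), ("chr1", 1000, 2000))
        # region spans the boundary; midpoint 1050 lies in the second TAD
        assert assign_to_domain(GenomicInterval("chr1", 900, 1200), tads) == 1

    def test_no_domain_on_chromosome(self):
        tads = iset(("chr2", 0, 1000))
        assert assign_to_domain(GenomicInterval("chr1", 100, 200), tads) is None

    def test_overlapping_domains_rejected_on_validation(self):
        with pytest.raises(ValueError):
            validate_non_overlapping(iset(("chr1", 0, 1000), ("chr1", 500, 1500)))
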