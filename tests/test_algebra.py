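"""Interval algebra: sort, merge, join, partition, subtract, intersect,
membership, flank and coverage statistics — checked against the canonical
worked example and against brute-force base-enumeration oracles."""

import pytest

from regionkit import (
    ChromosomeOrdering,
    GenomeTable,
    GenomicInterval,
    RegionSet,
    coverage_stats,
    flank_regions,
    in_region,
    intersect_regions,
    join_left,
    merge_regions,
    multijoin,
    sort_and_merge,
    sort_regions,
    subtract_regions,
)

from conftest import (
    oracle_intersect,
    oracle_join,
    oracle_merge,
    oracle_signatures,
    oracle_subtract_partial,
    oracle_subtract_whole,
    random_pair,
)

NAT = ChromosomeOrdering.natural
LEX = ChromosomeOrdering.lexicographic

NATURAL_SORTED = [
    "chr1:10-100", "chr1:101-200", "chr1:200-210", "chr1:211-212",
    "chr2:10-50", "chr2:40-60", "chr10:50-100", "chr20:1-5",
]
LEX_SORTED = [
    "chr1:10-100", "chr1:101-200", "chr1:200-210", "chr1:211-212",
    "chr10:50-100", "chr2:10-50", "chr2:40-60", "chr20:1-5",
]
MERGED = [
    "chr1:10-100", "chr1:101-210", "chr1:211-212",
    "chr10:50-100", "chr2:10-60", "chr20:1-5",
]


class TestSort:
    def test_natural_order(self, bundle):
        assert sort_regions(bundle.raw_example, NAT).to_strings() == NATURAL_SORTED

    def test_lexicographic_order(self, bundle):
        assert sort_regions(bundle.raw_example, LEX).to_strings() == LEX_SORTED

    def test_empty(self):
        assert sort_regions(RegionSet()).to_strings() == []

    def test_permutation_invariant(self, bundle):
        reversed_set = RegionSet(tuple(reversed(bundle.raw_example.intervals)))
        assert sort_regions(reversed_set, NAT).to_strings() == NATURAL_SORTED


class TestMerge:
    def test_example_merge(self, bundle):
        """Bookended chr1:101-200 + chr1:200-210 collapse; 1-bp gaps
        (chr1:100/101 and chr1:210/211) do not."""
        merged = merge_regions(bundle.raw_example, ordering=LEX)
        assert merged.to_strings() == MERGED
        assert merged.is_merged

    def test_snm_equals_merge_of_sort(self, bundle):
        assert sort_and_merge(bundle.raw_example).to_strings() == \
            merge_regions(sort_regions(bundle.raw_example, NAT)).to_strings()

    def test_idempotent(self, bundle):
        once = merge_regions(bundle.raw_example)
        assert merge_regions(once) == once

    def test_bookend_off_keeps_touching_intervals(self):
        rs = RegionSet.from_strings(["chr1:101-200", "chr1:200-210"])
        out = merge_regions(rs, bookend=False)
        assert out.to_strings() == ["chr1:101-200", "chr1:200-210"]
        assert merge_regions(rs).to_strings() == ["chr1:101-210"]

    def test_distance_bridges_gaps(self):
        rs = RegionSet.from_strings(["chr1:10-100", "chr1:101-200"])
        assert merge_regions(rs, distance=1).to_strings() == ["chr1:10-200"]
        assert merge_regions(rs, distance=0).to_strings() == \
            ["chr1:10-100", "chr1:101-200"]
        # boundary equality at the gap tolerance merges only with bookend on
        assert merge_regions(rs, distance=1, bookend=False).to_strings() == \
            ["chr1:10-100", "chr1:101-200"]

    def test_no_touching_invariant(self, bundle):
        for seed in range(20):
            a, _ = random_pair(seed)
            merged = merge_regions(a)
            by_chrom = {}
            for iv in merged:
                by_chrom.setdefault(iv.chrom, []).append(iv)
            for ivs in by_chrom.values():
                for prev, nxt in zip(ivs, ivs[1:]):
                    assert nxt.start > prev.end

    def test_matches_base_oracle(self):
        for seed in range(30):
            a, _ = random_pair(seed)
            assert set(merge_regions(a)) == oracle_merge(a)


class TestJoin:
    def test_example_join_table(self, bundle):
        rows = join_left(bundle.set_a, bundle.set_b)
        got = [(str(r.left), r.right_chrom, r.right_start, r.right_end)
               for r in rows]
        assert got == [
            ("chr1:10-100", ".", -1, -1),
            ("chr1:101-210", "chr1", 111, 250),
            ("chr1:211-212", "chr1", 111, 250),
            ("chr10:50-100", ".", -1, -1),
            ("chr2:10-60", "chr2", 40, 60),
            ("chr20:1-5", ".", -1, -1),
        ]

    def test_empty_right_gives_all_sentinels(self, bundle):
        rows = join_left(bundle.set_a, RegionSet())
        assert all(r.is_sentinel for r in rows)
        assert len(rows) == len(bundle.set_a)

    def test_matches_base_oracle(self):
        for seed in range(25):
            a, b = random_pair(seed)
            expected = oracle_join(a, b)
            rows = join_left(a, b)
            got: dict[GenomicInterval, set] = {}
            for r in rows:
                partners = got.setdefault(r.left, set())
                if not r.is_sentinel:
                    partners.add(
                        GenomicInterval(r.right_chrom, r.right_start,
                                        r.right_end))
            assert got == expected

    def test_rows_grouped_and_b_ordered(self):
        a = RegionSet.from_strings(["chr1:0-1000"])
        b = RegionSet.from_strings(["chr1:500-600", "chr1:100-200"])
        rows = join_left(a, b)
        assert [(r.right_start, r.right_end) for r in rows] == \
            [(100, 200), (500, 600)]


class TestMultijoin:
    def test_example_24_cells(self, bundle):
        labels, cells = multijoin([bundle.set_a, bundle.set_b, bundle.set_c])
        assert labels == ["a", "b", "c"]
        assert len(cells) == 24
        index = {str(c.cell): c for c in cells}
        assert index["chr1:1-10"].names == "b,c"
        assert index["chr1:1-10"].membership == (0, 1, 1)
        assert index["chr1:111-210"].names == "a,b,c"
        assert index["chr1:111-210"].n_overlaps == 3

    def test_uncovered_gaps_not_emitted(self, bundle):
        _, cells = multijoin([bundle.set_a, bundle.set_b, bundle.set_c])
        names = [str(c.cell) for c in cells]
        assert "chr20:5-6" not in names
        assert "chr20:1-5" in names and "chr20:6-7" in names

    def test_self_join(self, bundle):
        a = bundle.set_a
        _, cells = multijoin({"x": a, "y": a})
        assert [c.cell for c in cells] == list(a.intervals)
        assert all(c.n_overlaps == 2 for c in cells)

    def test_requires_two_sets(self, bundle):
        with pytest.raises(ValueError):
            multijoin([bundle.set_a])

    def test_tiling_matches_base_oracle(self):
        """Cells are disjoint, sorted, tile the union, and carry per-base
        correct membership."""
        for seed in range(25):
            a, b = random_pair(seed)
            c, _ = random_pair(seed + 500)
            c = RegionSet(c.intervals, label="c")
            labeled = {"a": a, "b": b, "c": c}
            labels, cells = multijoin(labeled)
            expected = oracle_signatures(labeled)
            got_bases = {}
            for cell in cells:
                sig = frozenset(lb for lb, bit in zip(labels, cell.membership)
                                if bit)
                for p in range(cell.cell.start, cell.cell.end):
                    base = (cell.cell.chrom, p)
                    assert base not in got_bases, "cells overlap"
                    got_bases[base] = sig
            assert got_bases == expected


class TestSubtract:
    def test_example_whole(self, bundle):
        out = subtract_regions(bundle.set_a, bundle.set_b)
        assert out.to_strings() == ["chr1:10-100", "chr10:50-100", "chr20:1-5"]

    def test_example_partial(self, bundle):
        out = subtract_regions(bundle.set_a, bundle.set_b, mode="partial",
                               ordering=NAT)
        assert out.to_strings() == [
            "chr1:10-100", "chr1:101-111", "chr2:10-40",
            "chr10:50-100", "chr20:1-5",
        ]

    def test_subtract_empty_is_identity(self, bundle):
        for mode in ("whole", "partial"):
            out = subtract_regions(bundle.set_a, RegionSet(), mode=mode)
            assert list(out) == list(bundle.set_a)

    def test_matches_base_oracle(self):
        for seed in range(25):
            a, b = random_pair(seed)
            assert set(subtract_regions(a, b, mode="partial")) == \
                oracle_subtract_partial(a, b)
            assert set(subtract_regions(a, b, mode="whole")) == \
                oracle_subtract_whole(a, b)

    def test_whole_mode_partitions_merged_a(self):
        """Every merged-a interval lands in exactly one of: the whole-mode
        output, or the non-sentinel join rows."""
        for seed in range(15):
            a, b = random_pair(seed)
            kept = set(subtract_regions(a, b, mode="whole"))
            joined = {r.left for r in join_left(a, b) if not r.is_sentinel}
            merged = set(merge_regions(a))
            assert kept | joined == merged
            assert not kept & joined


class TestIntersect:
    def test_example(self, bundle):
        out = intersect_regions(bundle.set_a, bundle.set_b)
        assert out.to_strings() == ["chr1:111-210", "chr1:211-212",
                                    "chr2:40-60"]

    def test_self_intersection_is_merge(self, bundle):
        raw = bundle.raw_example
        assert set(intersect_regions(raw, raw)) == set(merge_regions(raw))

    def test_matches_base_oracle(self):
        for seed in range(25):
            a, b = random_pair(seed)
            assert set(intersect_regions(a, b)) == oracle_intersect(a, b)


class TestInRegion:
    def test_example_vector(self, bundle):
        assert in_region(bundle.set_a, bundle.set_b) == \
            [False, True, True, False, True, False]

    def test_empty_b_all_false(self, bundle):
        assert in_region(bundle.set_a, RegionSet()) == [False] * 6

    def test_agrees_with_join_sentinels(self):
        for seed in range(20):
            a, b = random_pair(seed)
            a_merged = merge_regions(a)
            flags = in_region(a_merged, b)
            rows = join_left(a_merged, b)
            by_left = {}
            for r in rows:
                by_left.setdefault(r.left, []).append(r)
            assert flags == [not by_left[iv][0].is_sentinel
                             for iv in a_merged]


class TestFlank:
    def test_clipping_at_zero(self, bundle):
        out = flank_regions(bundle.set_b, upstream=5, downstream=5)
        strings = out.to_strings()
        # chr1:1-10 yields a clipped 1 bp up-flank and a full down-flank
        assert "chr1:0-1" in strings and "chr1:10-15" in strings

    def test_upstream_zero_emits_only_downstream(self):
        rs = RegionSet.from_strings(["chr1:100-200"])
        out = flank_regions(rs, upstream=0, downstream=7)
        assert out.to_strings() == ["chr1:200-207"]

    def test_genome_clipping_and_widths(self):
        genome = GenomeTable({"chr1": 210})
        rs = RegionSet.from_strings(["chr1:100-200"])
        out = flank_regions(rs, upstream=5, downstream=50, genome=genome)
        assert out.to_strings() == ["chr1:95-100", "chr1:200-210"]
        for iv in out:
            assert iv.width <= 50

    def test_flank_at_chromosome_start_dropped(self):
        rs = RegionSet.from_strings(["chr1:0-10"])
        out = flank_regions(rs, upstream=5, downstream=0)
        assert out.to_strings() == []

    def test_requires_positive_width(self, bundle):
        with pytest.raises(ValueError):
            flank_regions(bundle.set_a, upstream=0, downstream=0)


class TestCoverageStats:
    def test_example_totals(self, bundle):
        stats = coverage_stats(bundle.set_a, bundle.set_b)
        assert stats.total_bp == 304
        assert stats.shared_bp == 120

    def test_empty(self):
        assert coverage_stats(RegionSet()).total_bp == 0

    def test_conservation(self):
        """total_bp(partial subtract) + shared_bp == total_bp(a)."""
        for seed in range(25):
            a, b = random_pair(seed)
            stats = coverage_stats(a, b)
            left = coverage_stats(
                subtract_regions(a, b, mode="partial")).total_bp
            assert left + stats.shared_bp == stats.total_bp
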