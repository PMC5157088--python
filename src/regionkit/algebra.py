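"""Interval set operations: sort, merge, join, partition, subtract, intersect,
membership, flank and coverage statistics.

All operations are sweep-line based and deterministic.  Two conventions run
through the module and mirror the defaults of the classic BED engines:

* *Overlap* requires at least one shared base — bookended intervals
  (``prev.end == next.start``) never overlap.
* *Merging* at distance 0 collapses bookended intervals by default
  (``bookend=True``); pass ``bookend=False`` to require a strict overlap.

Operations that merge internally resolve their output ordering as follows:
an explicit ``ordering`` argument wins; otherwise a sort order recorded on
the input set is kept; otherwise the natural (version-sort) order is used.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import (
    ChromosomeOrdering,
    GenomeTable,
    GenomicInterval,
    RegionSet,
    chromosome_sort_key,
    interval_sort_key,
)

__all__ = [
    "JoinRow",
    "PartitionCell",
    "OverlapStats",
    "sort_regions",
    "merge_regions",
    "sort_and_merge",
    "join_left",
    "multijoin",
    "subtract_regions",
    "intersect_regions",
    "in_region",
    "flank_regions",
    "coverage_stats",
]

NATURAL = ChromosomeOrdering.natural


# ---------------------------------------------------------------------------
# sorting and merging

def sort_regions(
    rs: RegionSet, ordering: ChromosomeOrdering = NATURAL
) -> RegionSet:
    """Sort by chromosome under `ordering`, then by start, then end (stable)."""
    ivs = sorted(rs.intervals, key=lambda iv: interval_sort_key(iv, ordering))
    return RegionSet(ivs, label=rs.label, is_sorted=ordering,
                     is_merged=rs.is_merged)


def _resolve_ordering(
    ordering: ChromosomeOrdering | None, *sets: RegionSet
) -> ChromosomeOrdering:
    if ordering is not None:
        return ChromosomeOrdering(ordering)
    recorded = {rs.is_sorted for rs in sets}
    if len(recorded) == 1 and None not in recorded:
        return recorded.pop()
    return NATURAL


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for pairs in out.values():
        pairs.sort()
    return out


def _merge_pairs(
    pairs: Sequence[tuple[int, int]], distance: int, bookend: bool
) -> list[tuple[int, int]]:
    """Collapse sorted (start, end) pairs; `distance` is the gap tolerance."""
    merged: list[tuple[int, int]] = []
    for start, end in pairs:
        if merged:
            cur_start, cur_end = merged[-1]
            # boundary equality (gap == distance) merges only with bookend on
            joins = (start <= cur_end + distance) if bookend \
                else (start < cur_end + distance)
            if joins:
                merged[-1] = (cur_start, max(cur_end, end))
                continue
        merged.append((start, end))
    return merged


def _merged_map(
    rs: RegionSet, distance: int = 0, bookend: bool = True
) -> dict[str, list[tuple[int, int]]]:
    chrom_map = _by_chrom(rs.intervals)
    return {c: _merge_pairs(p, distance, bookend) for c, p in chrom_map.items()}


def _emit(
    chrom_map: Mapping[str, Sequence[tuple[int, int]]],
    ordering: ChromosomeOrdering,
    label: str | None = None,
    merged: bool = True,
) -> RegionSet:
    chroms = sorted(chrom_map, key=lambda c: chromosome_sort_key(c, ordering))
    ivs = [GenomicInterval(c, s, e) for c in chroms for s, e in chrom_map[c]]
    return RegionSet(ivs, label=label, is_sorted=ordering, is_merged=merged)


def merge_regions(
    rs: RegionSet,
    distance: int = 0,
    bookend: bool = True,
    ordering: ChromosomeOrdering | None = None,
) -> RegionSet:
    """Collapse overlapping (and, with `bookend`, touching) intervals.

    Runs of intervals on one chromosome where each starts within
    ``running end + distance`` are replaced by one interval spanning the run.
    The output is sorted and flagged merged.
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    resolved = _resolve_ordering(ordering, rs)
    return _emit(_merged_map(rs, distance, bookend), resolved, label=rs.label)


def sort_and_merge(rs: RegionSet) -> RegionSet:
    """Sort (natural order) and merge in one step; equals merge∘sort."""
    return merge_regions(rs, ordering=NATURAL)


def _prepared(rs: RegionSet, ordering: ChromosomeOrdering) -> RegionSet:
    """Merged form of `rs`, preserving its own order when already merged."""
    if rs.is_merged:
        return rs
    return merge_regions(rs, ordering=ordering)


# ---------------------------------------------------------------------------
# join

@dataclass(frozen=True)
class JoinRow:
    """One left interval paired with an overlapping right interval.

    A left interval with no overlapping right partner yields exactly one row
    with the sentinels ``right_chrom="."``, ``right_start=right_end=-1``.
    """

    left: GenomicInterval
    right_chrom: str = "."
    right_start: int = -1
    right_end: int = -1

    def __post_init__(self) -> None:
        sentinel = (self.right_chrom == ".", self.right_start == -1,
                    self.right_end == -1)
        if any(sentinel) and not all(sentinel):
            raise ValueError("sentinel fields must appear jointly")

    @property
    def is_sentinel(self) -> bool:
        return self.right_chrom == "."


def _overlapping(
    chrom_map: Mapping[str, Sequence[tuple[int, int]]],
    iv: GenomicInterval,
) -> list[tuple[int, int]]:
    """All merged (start, end) pairs sharing >= 1 base with `iv`."""
    pairs = chrom_map.get(iv.chrom, ())
    starts = [s for s, _ in pairs]
    # first candidate: the rightmost pair starting before iv.end could still
    # overlap; scan left from there while ends reach past iv.start
    hi = bisect_right(starts, iv.end - 1)
    hits = [(s, e) for s, e in pairs[:hi] if e > iv.start]
    return hits


def join_left(
    a: RegionSet,
    b: RegionSet,
    ordering: ChromosomeOrdering | None = None,
) -> list[JoinRow]:
    """Left outer join of `a` against `b` on >= 1 bp interval overlap.

    Both sets are merged internally first.  Each `a` interval produces one
    row per overlapping `b` interval (ordered by b start) or a single
    sentinel row when none overlap.
    """
    resolved = _resolve_ordering(ordering, a)
    a_m = _prepared(a, resolved)
    b_map = _merged_map(b)
    rows: list[JoinRow] = []
    for iv in a_m:
        hits = _overlapping(b_map, iv)
        if not hits:
            rows.append(JoinRow(iv))
        else:
            rows.extend(JoinRow(iv, iv.chrom, s, e) for s, e in hits)
    return rows


# ---------------------------------------------------------------------------
# multi-set partition join

@dataclass(frozen=True)
class PartitionCell:
    """An atomic sub-region annotated with which input sets cover it.

    ``membership`` maps each input label to 0/1 in input order; ``names`` is
    the comma-joined list of covering labels; ``n_overlaps`` counts them.
    Cells covered by no set are never emitted.
    """

    cell: GenomicInterval
    n_overlaps: int
    names: str
    membership: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n_overlaps != sum(self.membership):
            raise ValueError("n_overlaps must equal the number of set bits")
        if self.n_overlaps < 1:
            raise ValueError("cells covered by no set are never emitted")
        if self.n_overlaps != len(self.names.split(",")):
            raise ValueError("names must list exactly the covering labels")


def _as_labeled(
    sets: Sequence[RegionSet] | Mapping[str, RegionSet]
) -> tuple[list[str], list[RegionSet]]:
    if isinstance(sets, Mapping):
        return list(sets.keys()), list(sets.values())
    labels = [rs.label if rs.label is not None else f"set{i + 1}"
              for i, rs in enumerate(sets)]
    if len(set(labels)) != len(labels):
        raise ValueError("set labels must be unique")
    return labels, list(sets)


def _covers(pairs: Sequence[tuple[int, int]], start: int, end: int) -> bool:
    """True iff some merged pair fully contains [start, end)."""
    starts = [s for s, _ in pairs]
    i = bisect_right(starts, start) - 1
    return i >= 0 and pairs[i][1] >= end


def multijoin(
    sets: Sequence[RegionSet] | Mapping[str, RegionSet],
    ordering: ChromosomeOrdering | None = None,
) -> tuple[list[str], list[PartitionCell]]:
    """Partition the union of >= 2 labeled sets into annotated atomic cells.

    Per chromosome, every interval endpoint of every (internally merged) set
    is a breakpoint; consecutive breakpoints bound a candidate cell, which is
    emitted iff at least one set covers it.  Returns the labels (in input
    order) and the cells in sorted order.
    """
    labels, region_sets = _as_labeled(sets)
    if len(region_sets) < 2:
        raise ValueError("multijoin requires at least 2 region sets")
    resolved = _resolve_ordering(ordering, *region_sets)
    maps = [_merged_map(rs) for rs in region_sets]

    all_chroms = set()
    for m in maps:
        all_chroms.update(m)
    chroms = sorted(all_chroms, key=lambda c: chromosome_sort_key(c, resolved))

    cells: list[PartitionCell] = []
    for chrom in chroms:
        breakpoints = sorted({p for m in maps for s, e in m.get(chrom, ())
                              for p in (s, e)})
        for start, end in zip(breakpoints, breakpoints[1:]):
            membership = tuple(
                int(_covers(m.get(chrom, ()), start, end)) for m in maps
            )
            n = sum(membership)
            if n == 0:
                continue
            names = ",".join(lb for lb, bit in zip(labels, membership) if bit)
            cells.append(PartitionCell(GenomicInterval(chrom, start, end),
                                       n, names, membership))
    return labels, cells


# ---------------------------------------------------------------------------
# subtract / intersect / membership

def subtract_regions(
    a: RegionSet,
    b: RegionSet,
    mode: str = "whole",
    ordering: ChromosomeOrdering | None = None,
) -> RegionSet:
    """Regions of `a` not covered by `b`.

    ``mode="whole"`` keeps each merged `a` interval intact iff it shares no
    base with `b`; ``mode="partial"`` returns the base-level difference
    ``a \\ b`` as maximal intervals.
    """
    if mode not in ("whole", "partial"):
        raise ValueError(f"unknown subtract mode {mode!r}")
    resolved = _resolve_ordering(ordering, a)
    a_m = _prepared(a, resolved)
    b_map = _merged_map(b)
    if mode == "whole":
        ivs = [iv for iv in a_m if not _overlapping(b_map, iv)]
        return RegionSet(ivs, label=a.label, is_sorted=a_m.is_sorted,
                         is_merged=True)
    out: dict[str, list[tuple[int, int]]] = {}
    for iv in a_m:
        cursor = iv.start
        for s, e in _overlapping(b_map, iv):
            if s > cursor:
                out.setdefault(iv.chrom, []).append((cursor, s))
            cursor = max(cursor, e)
        if cursor < iv.end:
            out.setdefault(iv.chrom, []).append((cursor, iv.end))
    for pairs in out.values():
        pairs.sort()
    return _emit(out, resolved, label=a.label)


def intersect_regions(
    a: RegionSet,
    b: RegionSet,
    ordering: ChromosomeOrdering | None = None,
) -> RegionSet:
    """Base-level intersection ``a ∩ b`` as maximal intervals, sorted."""
    resolved = _resolve_ordering(ordering, a, b)
    a_map = _merged_map(a)
    b_map = _merged_map(b)
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, a_pairs in a_map.items():
        b_pairs = b_map.get(chrom)
        if not b_pairs:
            continue
        i = j = 0
        while i < len(a_pairs) and j < len(b_pairs):
            s = max(a_pairs[i][0], b_pairs[j][0])
            e = min(a_pairs[i][1], b_pairs[j][1])
            if s < e:
                out.setdefault(chrom, []).append((s, e))
            if a_pairs[i][1] <= b_pairs[j][1]:
                i += 1
            else:
                j += 1
    return _emit(out, resolved)


def in_region(a: RegionSet, b: RegionSet) -> list[bool]:
    """Per `a` interval (in its given order): does it overlap any `b` interval
    by >= 1 bp?  Consistent with `join_left` sentinels."""
    b_map = _merged_map(b)
    return [bool(_overlapping(b_map, iv)) for iv in a]


# ---------------------------------------------------------------------------
# flank and coverage

def flank_regions(
    rs: RegionSet,
    upstream: int = 0,
    downstream: int = 0,
    genome: GenomeTable | None = None,
    ordering: ChromosomeOrdering | None = None,
) -> RegionSet:
    """Flanks of the requested widths on each side of each interval.

    For ``[s, e)`` emit the up-flank ``[s-upstream, s)`` and down-flank
    ``[e, e+downstream)``, clipped at 0 and at the chromosome length when a
    genome table is given; flanks that become empty after clipping are
    dropped.  The output is sorted but deliberately not merged with the
    source intervals.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("flank widths must be non-negative")
    if upstream == 0 and downstream == 0:
        raise ValueError("at least one of upstream/downstream must be > 0")
    resolved = _resolve_ordering(ordering, rs)
    flanks: list[GenomicInterval] = []
    for iv in rs:
        limit = genome.get(iv.chrom) if genome is not None else None
        if upstream:
            s = max(0, iv.start - upstream)
            if s < iv.start:
                flanks.append(GenomicInterval(iv.chrom, s, iv.start))
        if downstream:
            e = iv.end + downstream
            if limit is not None:
                e = min(e, limit)
            if e > iv.end:
                flanks.append(GenomicInterval(iv.chrom, iv.end, e))
    flanks.sort(key=lambda iv: interval_sort_key(iv, resolved))
    return RegionSet(flanks, is_sorted=resolved, is_merged=False)


@dataclass(frozen=True)
class OverlapStats:
    """Width bookkeeping: total merged width and, optionally, shared width."""

    total_bp: int
    shared_bp: int | None = None


def coverage_stats(a: RegionSet, b: RegionSet | None = None) -> OverlapStats:
    """``total_bp`` = width of merge(a); ``shared_bp`` = width of a ∩ b."""
    total = sum(e - s for pairs in _merged_map(a).values() for s, e in pairs)
    if b is None:
        return OverlapStats(total)
    shared = sum(iv.width for iv in intersect_regions(a, b))
    return OverlapStats(total, shared)
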