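"""Shared fixtures and independent brute-force oracles.

The oracles work by base enumeration: every interval set is expanded to the
literal set of (chrom, position) bases it covers, and each operation is
recomputed from those base sets.  They are deliberately naive and share no
code with the sweep-line implementations they check; they are only usable
for small coordinates (< 10^4 in the property suites).
"""

from __future__ import annotations

import pytest

from regionkit import GenomicInterval, RegionSet, example_regions
from regionkit.fixtures import random_regions

# small genome for randomised property tests: coordinates < 10^4
TINY_GENOME = {"chrA": 3000, "chrB": 2500, "chr2": 2000}


@pytest.fixture(scope="session")
def bundle():
    return example_regions()


def random_pair(seed: int, n: int = 20, genome=TINY_GENOME):
    """Two seeded random sets over the tiny genome (widths up to 300 bp)."""
    a = random_regions(n, chroms=genome, width_range=(1, 300), seed=seed,
                       label="a")
    b = random_regions(n, chroms=genome, width_range=(1, 300),
                       seed=seed + 10_000, label="b")
    return a, b


# ---------------------------------------------------------------------------
# base-enumeration oracles

def covered_bases(rs: RegionSet) -> set[tuple[str, int]]:
    return {(iv.chrom, p) for iv in rs for p in range(iv.start, iv.end)}


def bases_to_intervals(bases: set[tuple[str, int]]) -> list[GenomicInterval]:
    """Maximal runs of contiguous covered bases, as intervals."""
    by_chrom: dict[str, list[int]] = {}
    for chrom, p in bases:
        by_chrom.setdefault(chrom, []).append(p)
    out = []
    for chrom, positions in by_chrom.items():
        positions.sort()
        run_start = prev = positions[0]
        for p in positions[1:]:
            if p != prev + 1:
                out.append(GenomicInterval(chrom, run_start, prev + 1))
                run_start = p
            prev = p
        out.append(GenomicInterval(chrom, run_start, prev + 1))
    return out


def oracle_merge(rs: RegionSet) -> set[GenomicInterval]:
    """Merged intervals at distance 0 with bookends collapsed: exactly the
    maximal contiguous runs of covered bases."""
    return set(bases_to_intervals(covered_bases(rs)))


def oracle_intersect(a: RegionSet, b: RegionSet) -> set[GenomicInterval]:
    return set(bases_to_intervals(covered_bases(a) & covered_bases(b)))


def oracle_subtract_partial(a: RegionSet, b: RegionSet) -> set[GenomicInterval]:
    return set(bases_to_intervals(covered_bases(a) - covered_bases(b)))


def oracle_subtract_whole(a: RegionSet, b: RegionSet) -> set[GenomicInterval]:
    b_bases = covered_bases(b)
    return {iv for iv in oracle_merge(a)
            if not ({(iv.chrom, p) for p in range(iv.start, iv.end)} & b_bases)}


def oracle_join(a: RegionSet, b: RegionSet) -> dict[GenomicInterval, set]:
    """Per merged-a interval: the set of merged-b intervals sharing a base."""
    b_merged = oracle_merge(b)
    out: dict[GenomicInterval, set] = {}
    for iv in oracle_merge(a):
        iv_bases = {(iv.chrom, p) for p in range(iv.start, iv.end)}
        out[iv] = {
            bv for bv in b_merged
            if {(bv.chrom, p) for p in range(bv.start, bv.end)} & iv_bases
        }
    return out


def oracle_signatures(
    labeled: dict[str, RegionSet]
) -> dict[tuple[str, int], frozenset]:
    """Per covered base: the frozenset of labels whose set covers it."""
    per_base: dict[tuple[str, int], set] = {}
    for label, rs in labeled.items():
        for base in covered_bases(rs):
            per_base.setdefault(base, set()).add(label)
    return {base: frozenset(sig) for base, sig in per_base.items()}
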