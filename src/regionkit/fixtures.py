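"""Deterministic example data and seeded random region generators.

`example_regions` rebuilds the canonical worked example used throughout the
package documentation and tests: an 8-interval unsorted set whose merge
gives set A, two further merged sets B and C chosen so that the three-way
partition of A/B/C produces a fixed 24-cell truth table, and a small
COSMIC-style coding-mutation VCF excerpt (six OR4F5 mutations on chromosome
1) padded with deterministic decoy records for query testing.  Everything is
generated in memory — no downloads, no binary files.

Sets A/B/C carry a lexicographic sort flag because the canonical outputs
list chromosomes in lexicographic order (chr1, chr10, chr2, chr20).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Sequence

from .core import ChromosomeOrdering, GenomicInterval, RegionSet

__all__ = [
    "FixtureBundle",
    "example_regions",
    "random_regions",
    "synthetic_vcf",
    "EXAMPLE_GENOME",
]

LEX = ChromosomeOrdering.lexicographic

# plausible lengths for the example chromosomes (hg38 scale)
EXAMPLE_GENOME = {
    "chr1": 248_956_422,
    "chr2": 242_193_529,
    "chr10": 133_797_422,
    "chr20": 64_444_167,
}


@dataclass(frozen=True)
class FixtureBundle:
    """The worked-example data: raw 8-interval set, merged sets A/B/C, and
    synthetic VCF content (as text lines)."""

    raw_example: RegionSet
    set_a: RegionSet
    set_b: RegionSet
    set_c: RegionSet
    cosmic_vcf: str


# fixed scrambled order (the pre-sort order is arbitrary; fixed so that
# sorting tests are non-trivial and reproducible)
_RAW = (
    "chr1:200-210",
    "chr20:1-5",
    "chr2:10-50",
    "chr1:101-200",
    "chr10:50-100",
    "chr1:10-100",
    "chr2:40-60",
    "chr1:211-212",
)

_SET_A = (
    "chr1:10-100",
    "chr1:101-210",
    "chr1:211-212",
    "chr10:50-100",
    "chr2:10-60",
    "chr20:1-5",
)

# B and C are pinned by the canonical join and 24-cell partition tables:
# each cell signature forces which sets cover it, so the merged inputs are
# uniquely reconstructible.
_SET_B = (
    "chr1:1-10",
    "chr1:111-250",
    "chr1:2000-2010",
    "chr10:100-150",
    "chr2:1-5",
    "chr2:40-60",
    "chr20:6-10",
)

_SET_C = (
    "chr1:1-10",
    "chr1:20-240",
    "chr10:110-150",
    "chr2:1-20",
    "chr2:30-60",
    "chr20:7-12",
)

# the six COSMIC coding mutations of the worked example (chromosome 1,
# OR4F5), exactly as displayed
_COSMIC_CORE = (
    (69345, "COSM911918", "C", "A",
     "GENE=OR4F5;STRAND=+;CDS=c.255C>A;AA=p.I85I;CNT=1"),
    (69523, "COSM426644", "G", "T",
     "GENE=OR4F5;STRAND=+;CDS=c.433G>T;AA=p.G145C;CNT=1"),
    (69538, "COSM75742", "G", "A",
     "GENE=OR4F5;STRAND=+;CDS=c.448G>A;AA=p.V150M;CNT=1"),
    (69539, "COSM1343690", "T", "C",
     "GENE=OR4F5;STRAND=+;CDS=c.449T>C;AA=p.V150A;CNT=1"),
    (69540, "COSM1560546", "G", "T",
     "GENE=OR4F5;STRAND=+;CDS=c.450G>T;AA=p.V150V;CNT=1"),
    (69569, "COSM1599955", "T", "C",
     "GENE=OR4F5;STRAND=+;CDS=c.479T>C;AA=p.L160P;CNT=2"),
)

# deterministic decoys: outside 1:1000-100000, some inside 1:1000000-1100000
_DECOYS_OUTSIDE = (
    ("1", 500, "DECOY_LOW1", "A", "G", "GENE=SYN1;CNT=1"),
    ("1", 200500, "DECOY_MID1", "C", "T", "GENE=SYN2;CNT=1"),
    ("1", 2000000, "DECOY_HIGH1", "G", "C", "GENE=SYN3;CNT=1"),
    ("2", 69345, "DECOY_CHR2", "T", "A", "GENE=SYN4;CNT=1"),
)
_DECOYS_WINDOW2 = (
    ("1", 1000500, "DECOY_W2A", "A", "T", "GENE=SYN5;CNT=1"),
    ("1", 1050000, "DECOY_W2B", "G", "A", "GENE=SYN6;CNT=1"),
)

_VCF_HEADER = (
    "##fileformat=VCFv4.1",
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene name">',
    '##INFO=<ID=STRAND,Number=1,Type=String,Description="Gene strand">',
    '##INFO=<ID=CDS,Number=1,Type=String,Description="CDS annotation">',
    '##INFO=<ID=AA,Number=1,Type=String,Description="Peptide annotation">',
    '##INFO=<ID=CNT,Number=1,Type=Integer,Description="Sample count">',
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
)


def _cosmic_vcf_text() -> str:
    rows = [("1", pos, vid, ref, alt, info)
            for pos, vid, ref, alt, info in _COSMIC_CORE]
    rows += list(_DECOYS_OUTSIDE) + list(_DECOYS_WINDOW2)
    # position-sorted within chromosome, chromosomes in file order 1, 2
    rows.sort(key=lambda r: (r[0], r[1]))
    lines = list(_VCF_HEADER)
    lines += [f"{c}\t{p}\t{i}\t{r}\t{a}\t.\t.\t{info}"
              for c, p, i, r, a, info in rows]
    return "\n".join(lines) + "\n"


def example_regions() -> FixtureBundle:
    """Build the worked-example bundle; self-consistent by construction
    (merge(raw_example) == set_a, and A/B/C reproduce the canonical join and
    partition tables)."""
    return FixtureBundle(
        raw_example=RegionSet.from_strings(_RAW, label="raw"),
        set_a=RegionSet.from_strings(_SET_A, label="a", is_sorted=LEX,
                                     is_merged=True),
        set_b=RegionSet.from_strings(_SET_B, label="b", is_sorted=LEX,
                                     is_merged=True),
        set_c=RegionSet.from_strings(_SET_C, label="c", is_sorted=LEX,
                                     is_merged=True),
        cosmic_vcf=_cosmic_vcf_text(),
    )


def synthetic_vcf(path) -> None:
    """Write the synthetic COSMIC-style VCF (core records + decoys)."""
    text = _cosmic_vcf_text()
    if str(path).endswith(".gz"):
        import gzip

        with gzip.open(path, "wt", encoding="utf-8") as fh:
            fh.write(text)
    else:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write(text)


def random_regions(
    n: int,
    chroms: dict[str, int] | None = None,
    width_range: tuple[int, int] = (1, 100),
    seed: int = 0,
    label: str | None = None,
) -> RegionSet:
    """Seeded uniform random intervals, clipped to chromosome ends.

    Positions are uniform over each chromosome, widths uniform in
    ``width_range``; the same seed always yields the same set.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    lo, hi = width_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid width range {width_range}")
    if chroms is None:
        chroms = EXAMPLE_GENOME
    names = list(chroms)
    rng = random.Random(seed)
    ivs = []
    for _ in range(n):
        chrom = rng.choice(names)
        length = chroms[chrom]
        width = rng.randint(lo, hi)
        start = rng.randrange(0, length)  # start < length, so end > start
        end = min(start + width, length)
        ivs.append(GenomicInterval(chrom, start, end))
    return RegionSet(tuple(ivs), label=label)
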