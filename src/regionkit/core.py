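"""Coordinate model, region-string codec, chromosome orderings and validation.

The universal currency is the half-open genomic interval ``[start, end)`` on a
named chromosome, 0-based — identical to the first three BED columns.  Region
strings (``"chr1:10-100"``) use the same convention, so string and tabular
representations interconvert without any coordinate shift.

Two total orders over chromosome names are provided:

``natural``
    Version-style ordering: an optional ``chr`` prefix is ignored
    (case-insensitively), the remainder is tokenized into alternating
    numeric/alphabetic runs, numeric runs compare as integers, and numeric
    runs sort before alphabetic ones at the same position.  This yields
    ``chr1 < chr2 < chr10 < chr22 < chrM < chrX < chrY``.

``lexicographic``
    Plain byte-wise comparison of the full name, so ``chr10 < chr2``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "ChromosomeOrdering",
    "GenomeTable",
    "RegionParseError",
    "ValidationIssue",
    "ValidationReport",
    "parse_region",
    "format_region",
    "compare_chromosomes",
    "chromosome_sort_key",
    "interval_sort_key",
    "validate_regions",
]


class RegionParseError(ValueError):
    """Raised for malformed region strings or invalid coordinates."""


@dataclass(frozen=True, order=False)
class GenomicInterval:
    """A half-open region ``[start, end)`` on chromosome ``chrom``.

    ``start`` is 0-based inclusive, ``end`` exclusive; empty intervals are
    rejected so every interval covers at least one base.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if re.search(r"[\s:\-]", self.chrom):
            raise ValueError(
                f"chromosome name {self.chrom!r} contains whitespace, ':' or '-'"
            )
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval: start={self.start}, end={self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base.

        Bookended intervals (``self.end == other.start``) do NOT overlap.
        """
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return format_region(self)


class ChromosomeOrdering(str, Enum):
    """Which total order to use over chromosome names."""

    natural = "natural"
    lexicographic = "lexicographic"


_TOKEN_RE = re.compile(r"\d+|\D+")


def _natural_key(name: str) -> tuple:
    body = name[3:] if name[:3].lower() == "chr" else name
    tokens = []
    for run in _TOKEN_RE.findall(body):
        if run.isdigit():
            tokens.append((0, int(run), ""))
        else:
            tokens.append((1, 0, run.lower()))
    # raw-name tiebreak keeps the order total (antisymmetric) even for names
    # that differ only by case or by the chr prefix
    return (tuple(tokens), name)


def chromosome_sort_key(name: str, ordering: ChromosomeOrdering):
    """A sort key realising `ordering` over chromosome names."""
    if ordering is ChromosomeOrdering.natural:
        return _natural_key(name)
    return name.encode("utf-8")


def compare_chromosomes(a: str, b: str, ordering: ChromosomeOrdering) -> int:
    """Three-way comparison of chromosome names under `ordering`.

    Returns -1, 0 or +1.  Zero only for identical names, so each mode is a
    total order.
    """
    if not a or not b:
        raise ValueError("chromosome names must be non-empty")
    ka, kb = chromosome_sort_key(a, ordering), chromosome_sort_key(b, ordering)
    return (ka > kb) - (ka < kb)


def interval_sort_key(iv: GenomicInterval, ordering: ChromosomeOrdering):
    """Sort key for intervals: chromosome under `ordering`, then start, end."""
    return (chromosome_sort_key(iv.chrom, ordering), iv.start, iv.end)


_REGION_RE = re.compile(r"^([^:\s]+):(-?\d+)-(-?\d+)$")


def parse_region(text: str) -> GenomicInterval:
    """Parse a ``chrom:start-end`` region string into a `GenomicInterval`.

    Coordinates are 0-based half-open, matching BED columns.  Surrounding
    whitespace is tolerated; anything else malformed raises
    `RegionParseError` with a reason.
    """
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise RegionParseError(
            f"malformed region string {text!r}: expected 'chrom:start-end'"
        )
    chrom, start_s, end_s = m.groups()
    start, end = int(start_s), int(end_s)
    if start < 0:
        raise RegionParseError(f"negative start in {text!r}")
    if end <= start:
        raise RegionParseError(
            f"empty interval in {text!r}: end must exceed start"
        )
    return GenomicInterval(chrom, start, end)


def format_region(iv: GenomicInterval) -> str:
    """Inverse of `parse_region`: ``chrom:start-end`` with no padding."""
    return f"{iv.chrom}:{iv.start}-{iv.end}"


@dataclass
class RegionSet:
    """An ordered collection of intervals with sortedness/mergedness flags.

    ``is_sorted`` records the ordering the intervals are sorted under (or
    ``None`` when no ordering is known); ``is_merged`` asserts that no two
    intervals on the same chromosome overlap or touch.
    """

    intervals: tuple[GenomicInterval, ...] = ()
    label: str | None = None
    is_sorted: ChromosomeOrdering | None = None
    is_merged: bool = False

    def __post_init__(self) -> None:
        self.intervals = tuple(self.intervals)

    @classmethod
    def from_strings(
        cls,
        regions: Iterable[str],
        label: str | None = None,
        is_sorted: ChromosomeOrdering | None = None,
        is_merged: bool = False,
    ) -> "RegionSet":
        ivs = tuple(parse_region(r) for r in regions)
        return cls(ivs, label=label, is_sorted=is_sorted, is_merged=is_merged)

    def to_strings(self) -> list[str]:
        return [format_region(iv) for iv in self.intervals]

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.intervals == other.intervals


class GenomeTable(Mapping[str, int]):
    """Mapping chromosome name -> length in bp, used for clipping/validation."""

    def __init__(self, lengths: Mapping[str, int]):
        for name, length in lengths.items():
            if length <= 0:
                raise ValueError(f"non-positive length for {name!r}: {length}")
        self._lengths = dict(lengths)

    @classmethod
    def from_file(cls, path) -> "GenomeTable":
        """Read a BEDTools-style genome file: ``chrom<TAB>length``, no header."""
        lengths: dict[str, int] = {}
        with open(path, "rt", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 'chrom<TAB>length'"
                    )
                name = parts[0]
                if name in lengths:
                    raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
                try:
                    lengths[name] = int(parts[1])
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-integer length {parts[1]!r}"
                    ) from None
        return cls(lengths)

    def __getitem__(self, name: str) -> int:
        return self._lengths[name]

    def __iter__(self):
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)


@dataclass(frozen=True)
class ValidationIssue:
    index: int
    interval: GenomicInterval
    reason: str


@dataclass
class ValidationReport:
    """Per-interval pass/fail findings; never raises on content."""

    passed: list[bool] = field(default_factory=list)
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(self.passed)


def validate_regions(
    rs: RegionSet,
    genome: GenomeTable | None = None,
    check_chr: bool = False,
) -> ValidationReport:
    """Flag intervals that fall outside a genome or lack a ``chr`` prefix.

    With a genome table, intervals on unknown chromosomes or extending past
    the chromosome end are flagged.  With ``check_chr`` on, names lacking a
    case-sensitive ``chr`` prefix are flagged.  Purely observational.
    """
    report = ValidationReport()
    for i, iv in enumerate(rs):
        reasons = []
        if check_chr and not iv.chrom.startswith("chr"):
            reasons.append("missing chr prefix")
        if genome is not None:
            if iv.chrom not in genome:
                reasons.append("unknown chromosome")
            elif iv.end > genome[iv.chrom]:
                reasons.append(
                    f"end {iv.end} exceeds chromosome length {genome[iv.chrom]}"
                )
        report.passed.append(not reasons)
        for reason in reasons:
            report.issues.append(ValidationIssue(i, iv, reason))
    return report
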