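"""Readers/writers for BED and region-string files, plus structural converters.

BED here is the UCSC dialect: tab-separated, 0-based half-open, ``#``/
``track``/``browser`` lines skipped, trailing columns beyond the first three
carried opaquely and byte-exactly.  Files ending in ``.gz`` are read and
written gzip-compressed transparently.

Region strings and BED share the same coordinate convention, so conversion
between them copies coordinates verbatim — no ±1 shift in either direction.
A clearly-labelled 1-based inclusive table export is available for closed-
interval frameworks; it is never the default.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

from .core import GenomicInterval, RegionSet, parse_region, format_region

__all__ = [
    "BedRow",
    "BedParseError",
    "read_bed",
    "write_bed",
    "regions_to_table",
    "table_to_regions",
    "read_region_file",
    "write_region_file",
    "table_to_one_based",
]


class BedParseError(ValueError):
    """Raised with the offending line number for malformed BED content."""


@dataclass(frozen=True)
class BedRow:
    """One BED line: coordinates plus opaque trailing fields."""

    chrom: str
    start: int
    end: int
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval: start={self.start}, end={self.end}"
            )

    def to_line(self) -> str:
        return "\t".join((self.chrom, str(self.start), str(self.end))
                         + self.extra)


def _open_text(path, mode: str) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t", encoding="utf-8")
    return open(path, mode + "t", encoding="utf-8")


_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(path) -> list[BedRow]:
    """Read a BED3+ file in file order; no sorting, no coordinate edits.

    Raises `BedParseError` naming the line number for rows with fewer than
    three columns, non-integer or inverted coordinates.
    """
    rows: list[BedRow] = []
    with _open_text(path, "r") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or any(line.startswith(p) for p in _SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected at least 3 tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{fields[1]!r}, {fields[2]!r}"
                ) from None
            try:
                rows.append(BedRow(fields[0], start, end, tuple(fields[3:])))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
    return rows


def write_bed(rows: Iterable[BedRow], path) -> None:
    """Write tab-separated BED lines, no header; inverse of `read_bed`."""
    with _open_text(path, "w") as fh:
        for row in rows:
            fh.write(row.to_line() + "\n")


def regions_to_table(rs: RegionSet) -> list[BedRow]:
    """Lossless RegionSet -> BED rows; row order follows the set order."""
    return [BedRow(iv.chrom, iv.start, iv.end) for iv in rs]


def table_to_regions(rows: Sequence[BedRow], label: str | None = None) -> RegionSet:
    """Lossless BED rows -> RegionSet; preserves row order, never sorts."""
    return RegionSet(
        tuple(GenomicInterval(r.chrom, r.start, r.end) for r in rows),
        label=label,
    )


def table_to_one_based(rows: Sequence[BedRow]) -> list[tuple[str, int, int]]:
    """1-based inclusive (chrom, start+1, end) tuples for closed-interval
    frameworks.  Interoperability export only — not the native convention."""
    return [(r.chrom, r.start + 1, r.end) for r in rows]


def read_region_file(path, label: str | None = None) -> RegionSet:
    """Read a region-string list: one ``chrom:start-end`` per line, UTF-8,
    ``#`` comment lines and blank lines ignored."""
    regions: list[GenomicInterval] = []
    with _open_text(path, "r") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            regions.append(parse_region(line))
    return RegionSet(tuple(regions), label=label)


def write_region_file(rs: RegionSet, path) -> None:
    """Write one region string per line."""
    with _open_text(path, "w") as fh:
        for iv in rs:
            fh.write(format_region(iv) + "\n")
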