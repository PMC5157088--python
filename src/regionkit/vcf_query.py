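"""Minimal VCF parsing and tabix-style region extraction.

Only the eight fixed VCF columns are modelled (no FORMAT/sample columns);
INFO is carried as an opaque string.  Region queries follow the tabix
convention — ``chrom:start-end`` with **1-based inclusive** bounds — which is
deliberately different from this library's native half-open region strings.
Retrieval is a pure-text scan over the (plain or gzip) file; results always
match a naive linear filter, in file order, deduplicated across overlapping
query windows.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from typing import IO, Sequence

__all__ = [
    "VcfRecord",
    "VcfParseError",
    "VcfQueryError",
    "read_vcf",
    "query_vcf",
    "records_to_table",
    "write_vcf",
]


class VcfParseError(ValueError):
    """Malformed VCF content; message names the offending line."""


class VcfQueryError(ValueError):
    """Malformed or rejected tabix-style query string."""


@dataclass(frozen=True)
class VcfRecord:
    """One VCF data row.  ``pos`` is 1-based; "." maps to ``None`` for the
    optional fields."""

    chrom: str
    pos: int
    id: str | None
    ref: str
    alt: str
    qual: float | None
    filter: str | None
    info: str

    def to_line(self) -> str:
        def dot(v) -> str:
            return "." if v is None else str(v)

        qual = "." if self.qual is None else (
            f"{self.qual:g}" if isinstance(self.qual, float) else str(self.qual)
        )
        return "\t".join((self.chrom, str(self.pos), dot(self.id), self.ref,
                          self.alt, qual, dot(self.filter), self.info))


def _open_text(path) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _parse_record(fields: list[str], lineno: int, path) -> VcfRecord:
    if len(fields) < 8:
        raise VcfParseError(
            f"{path}:{lineno}: expected at least 8 columns, got {len(fields)}"
        )
    try:
        pos = int(fields[1])
    except ValueError:
        raise VcfParseError(
            f"{path}:{lineno}: non-integer POS {fields[1]!r}"
        ) from None
    if pos < 1:
        raise VcfParseError(f"{path}:{lineno}: POS must be >= 1, got {pos}")
    if not fields[3] or fields[3] == ".":
        raise VcfParseError(f"{path}:{lineno}: REF must be non-empty")

    def opt(v: str) -> str | None:
        return None if v == "." else v

    qual = None if fields[5] == "." else float(fields[5])
    return VcfRecord(fields[0], pos, opt(fields[2]), fields[3], fields[4],
                     qual, opt(fields[6]), fields[7])


def read_vcf(path) -> tuple[list[str], list[VcfRecord]]:
    """Read a plain or gzip VCF; returns (header lines, records in file order).

    Header lines ("##" meta lines and the "#CHROM" column header) are
    preserved verbatim.  A missing "#CHROM" header is an error.
    """
    header: list[str] = []
    records: list[VcfRecord] = []
    seen_chrom_header = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                header.append(line)
                if line.startswith("#CHROM"):
                    seen_chrom_header = True
                continue
            if not line:
                continue
            if not seen_chrom_header:
                raise VcfParseError(
                    f"{path}:{lineno}: data line before the #CHROM header"
                )
            records.append(_parse_record(line.split("\t"), lineno, path))
    if not seen_chrom_header:
        raise VcfParseError(f"{path}: no #CHROM header line found")
    return header, records


_QUERY_RE = re.compile(r"^([^:\s]+):(\d+)-(\d+)$")


def _parse_query(text: str, check_chr: bool) -> tuple[str, int, int]:
    m = _QUERY_RE.match(text.strip())
    if m is None:
        raise VcfQueryError(
            f"malformed tabix query {text!r}: expected 'chrom:start-end' "
            f"with 1-based inclusive bounds"
        )
    chrom, start_s, end_s = m.groups()
    start, end = int(start_s), int(end_s)
    if start < 1 or end < start:
        raise VcfQueryError(f"invalid 1-based inclusive bounds in {text!r}")
    if check_chr and not chrom.startswith("chr"):
        raise VcfQueryError(
            f"query chromosome {chrom!r} lacks the 'chr' prefix "
            f"(pass check_chr=False if the file uses bare names)"
        )
    return chrom, start, end


def query_vcf(
    regions: Sequence[str] | str,
    path,
    check_chr: bool = False,
) -> list[VcfRecord]:
    """Tabix-style extraction: records with ``start <= POS <= end``.

    Query bounds are 1-based inclusive.  Records are returned in file order
    and deduplicated when query windows overlap.  An absent chromosome simply
    yields no records.
    """
    if isinstance(regions, str):
        regions = [regions]
    windows = [_parse_query(r, check_chr) for r in regions]
    _, records = read_vcf(path)
    hits: list[VcfRecord] = []
    for rec in records:
        if any(c == rec.chrom and s <= rec.pos <= e for c, s, e in windows):
            hits.append(rec)
    return hits


def records_to_table(records: Sequence[VcfRecord]) -> list[list[str]]:
    """Tab-ready rows with the fixed CHROM..INFO column layout; missing
    values rendered as "."."""
    return [rec.to_line().split("\t") for rec in records]


def write_vcf(header: Sequence[str], records: Sequence[VcfRecord], path) -> None:
    """Re-serialize records under their original header."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt", encoding="utf-8") as fh:
        for line in header:
            fh.write(line + "\n")
        for rec in records:
            fh.write(rec.to_line() + "\n")
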