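"""Multi-set overlap quantification backing 2- to 5-way Venn output.

Two feature modes, both producing mutually exclusive categories that sum to
the union of all inputs:

``bp``
    Base-pair accounting: the union is partitioned into atomic cells
    (see `regionkit.algebra.multijoin`) and cell widths are summed per
    membership signature.

``interval``
    Atomic-interval counting: the union is merged into maximal "atomic
    intervals"; each atomic interval belongs to set S iff S covers at least
    ``fraction`` of its width; atomic intervals are counted per signature.

Rendering is left to downstream tools (matplotlib-venn, UpSet, ...); the
summary serializes to a small signature/amount table or JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

from .algebra import _merged_map, _overlapping, merge_regions, multijoin
from .core import RegionSet

__all__ = ["OverlapSummary", "venn_counts", "MIN_FRACTION"]

# default membership threshold in interval mode: any >= 1 bp overlap counts
MIN_FRACTION = 1e-9


@dataclass(frozen=True)
class OverlapSummary:
    """Amounts (bp or interval counts) per non-empty membership signature.

    Signatures are frozensets of labels; in bp mode the amounts sum to the
    total width of the union of all input sets.
    """

    labels: tuple[str, ...]
    feature_mode: str
    fraction: float
    counts: Mapping[frozenset, int]

    def amount(self, *labels: str) -> int:
        """Amount for the exact signature made of `labels` (0 if absent)."""
        return self.counts.get(frozenset(labels), 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def _signature_rows(self) -> list[tuple[str, int]]:
        def key(sig: frozenset) -> tuple:
            return (len(sig), tuple(lb for lb in self.labels if lb in sig))

        return [
            ("&".join(lb for lb in self.labels if lb in sig), amt)
            for sig, amt in sorted(self.counts.items(), key=lambda kv: key(kv[0]))
        ]

    def to_tsv(self) -> str:
        lines = [f"# feature={self.feature_mode} fraction={self.fraction:g}",
                 "signature\tamount"]
        lines += [f"{sig}\t{amt}" for sig, amt in self._signature_rows()]
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature": self.feature_mode,
                "fraction": self.fraction,
                "labels": list(self.labels),
                "counts": {sig: amt for sig, amt in self._signature_rows()},
            },
            indent=2,
        )


def venn_counts(
    sets: Sequence[RegionSet] | Mapping[str, RegionSet],
    feature_mode: str = "bp",
    fraction: float = MIN_FRACTION,
) -> OverlapSummary:
    """Quantify exclusive and shared coverage of 2 to 5 labeled region sets.

    See the module docstring for the two feature modes.  ``fraction`` (in
    (0, 1]) applies only in interval mode; at its tiny default any positive
    overlap grants membership.
    """
    from .algebra import _as_labeled  # shared label handling

    labels, region_sets = _as_labeled(sets)
    if not 2 <= len(region_sets) <= 5:
        raise ValueError(
            f"venn summaries support 2 to 5 sets, got {len(region_sets)}"
        )
    if feature_mode not in ("bp", "interval"):
        raise ValueError(f"unknown feature mode {feature_mode!r}")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")

    counts: dict[frozenset, int] = {}
    if feature_mode == "bp":
        _, cells = multijoin(dict(zip(labels, region_sets)))
        for cell in cells:
            sig = frozenset(lb for lb, bit in zip(labels, cell.membership) if bit)
            counts[sig] = counts.get(sig, 0) + cell.cell.width
    else:
        union = merge_regions(
            RegionSet(tuple(iv for rs in region_sets for iv in rs))
        )
        maps = [_merged_map(rs) for rs in region_sets]
        for atom in union:
            sig = set()
            for lb, m in zip(labels, maps):
                covered = sum(
                    min(e, atom.end) - max(s, atom.start)
                    for s, e in _overlapping(m, atom)
                )
                if covered >= fraction * atom.width:
                    sig.add(lb)
            if sig:
                fs = frozenset(sig)
                counts[fs] = counts.get(fs, 0) + 1
    return OverlapSummary(tuple(labels), feature_mode, fraction, counts)
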