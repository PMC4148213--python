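"""Genomic intervals and coordinate conventions.

All coordinates in this package are 1-based and inclusive at both ends,
matching the way assembly positions are quoted in linkage and fine-mapping
studies ("70,468,129-70,487,067 bp").  BED export converts to the 0-based
half-open convention; a write/read round trip is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, both-ends-inclusive chromosome span.

    Invariants: ``start >= 1`` and ``end >= start``; the length in bp is
    ``end - start + 1`` and is always positive.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int, chrom: Optional[str] = None) -> bool:
        if chrom is not None and chrom != self.chrom:
            return False
        return self.start <= position <= self.end

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start:,}-{self.end:,}"


def interval_length_kb(interval: GenomicInterval) -> float:
    """Span length in kb, rounded half-up to one decimal.

    A single base rounds to 0.0 kb.  At kb scale the printed sizes of
    mapping intervals are insensitive to the inclusive/exclusive +-1 bp
    convention.
    """
    kb = Decimal(interval.length_bp) / Decimal(1000)
    return float(kb.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def intersect(a: GenomicInterval, b: GenomicInterval) -> Optional[GenomicInterval]:
    """Overlap of two intervals, or None when disjoint or on different chromosomes."""
    if a.chrom != b.chrom:
        return None
    start = max(a.start, b.start)
    end = min(a.end, b.end)
    if end < start:
        return None
    return GenomicInterval(a.chrom, start, end)


def write_intervals(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as 3-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\n")


def read_intervals(path) -> list[GenomicInterval]:
    """Read a 3-column BED file back into 1-based inclusive intervals."""
    out: list[GenomicInterval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed BED line {lineno}: {line!r}")
        chrom, start0, end = fields[0], int(fields[1]), int(fields[2])
        out.append(GenomicInterval(chrom, start0 + 1, end))
    return out


# -- coordinate arithmetic relative to a translation start ---------------------
#
# Promoter-region variants are quoted relative to the A of the initiator ATG,
# which is position +1; upstream positions are negative and there is no
# position 0 (standard CDS-relative numbering).

def atg_position(anchor_pos: int, anchor_offset: int) -> int:
    """Genomic position of the ATG A given one position with a known offset."""
    if anchor_offset == 0:
        raise ValueError("offset 0 does not exist in +1-based CDS numbering")
    if anchor_offset < 0:
        return anchor_pos - anchor_offset
    return anchor_pos - anchor_offset + 1


def offset_from_atg(position: int, atg_pos: int) -> int:
    """CDS-relative offset of a genomic position (negative upstream, +1 = ATG A)."""
    if position < atg_pos:
        return position - atg_pos
    return position - atg_pos + 1
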