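"""Genomic interval primitives.

All coordinates in this package are BED-style: 0-based, half-open
``[start, end)``.  1-based inclusive coordinates exist only at the
HMMER-parse boundary (see :mod:`dupdepth.annotation`).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware genomic interval in BED convention.

    Parameters
    ----------
    chrom : str
        Sequence (chromosome/contig) name.
    start : int
        0-based inclusive start offset.
    end : int
        Exclusive end offset; must satisfy ``0 <= start < end``.
    strand : str
        ``"+"`` or ``"-"``; defaults to ``"+"``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def span(self, other: "GenomicInterval") -> "GenomicInterval":
        """Smallest interval covering self and ``other`` (same chrom)."""
        if self.chrom != other.chrom:
            raise ValueError("cannot span intervals on different sequences")
        return GenomicInterval(
            self.chrom, min(self.start, other.start), max(self.end, other.end), self.strand
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals per chromosome; strand is dropped to '+'."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def subtract_intervals(
    intervals: list[GenomicInterval], exclusions: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Remove every base covered by ``exclusions`` from ``intervals``."""
    excl = merge_intervals(exclusions)
    out: list[GenomicInterval] = []
    for iv in intervals:
        pieces = [(iv.start, iv.end)]
        for ex in excl:
            if ex.chrom != iv.chrom:
                continue
            nxt = []
            for s, e in pieces:
                if ex.end <= s or ex.start >= e:
                    nxt.append((s, e))
                    continue
                if ex.start > s:
                    nxt.append((s, ex.start))
                if ex.end < e:
                    nxt.append((ex.end, e))
            pieces = nxt
        out.extend(GenomicInterval(iv.chrom, s, e, iv.strand) for s, e in pieces)
    return out
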