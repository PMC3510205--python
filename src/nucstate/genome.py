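"""Core genomic domain types.

All coordinates in this package are 0-based, half-open (BED convention).
SAM/GTF inputs are converted at the parsing boundary and never leak their
1-based dialects inward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """A gene with exon structure; the unit of genic quantification.

    ``exons`` are sorted, disjoint and contained in ``span``.  The TSS is the
    first transcribed base (``span.start`` on "+", ``span.end - 1`` on "-")
    and the TES the last.
    """

    gene_id: str
    span: GenomicInterval
    exons: tuple = ()

    def __post_init__(self) -> None:
        if self.span.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: span must be stranded")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: at least one exon required")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        prev_end = None
        for ex in exons:
            if ex.chrom != self.span.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if ex.start < self.span.start or ex.end > self.span.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene span")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = ex.end
        object.__setattr__(self, "exons", exons)

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def tss(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end - 1

    @property
    def tes(self) -> int:
        return self.span.end - 1 if self.strand == "+" else self.span.start

    @property
    def length(self) -> int:
        return len(self.span)

    @property
    def introns(self) -> tuple:
        """Gaps between consecutive exons, as unstranded intervals."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start))
        return tuple(out)


@dataclass(frozen=True)
class AlignedTag:
    """One aligned sequencing tag (a single mate, not the fragment)."""

    interval: GenomicInterval
    mate_interval: Optional[GenomicInterval] = None
    library_id: str = ""

    def __post_init__(self) -> None:
        if self.mate_interval is not None:
            if self.mate_interval.chrom != self.interval.chrom:
                raise ValueError("mates must be on the same chromosome")

    @property
    def strand(self) -> str:
        return self.interval.strand


def merge_intervals(
    intervals: Sequence[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals closer than or equal to ``max_gap`` bp, per chromosome.

    Strand is ignored; merged intervals carry strand ".".
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= max_gap:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out
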