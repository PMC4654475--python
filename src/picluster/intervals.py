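"""Genomic intervals and BED12-derived gene models.

All coordinates in the package are 0-based half-open (BED convention).
WIG input, which is 1-based, is shifted on read so that a single
convention holds internally.
"""
from __future__ import annotations

from dataclasses import dataclass, field

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(
            self.chrom, self.start + offset, self.end + offset, self.strand
        )


def total_length(intervals: list[GenomicInterval]) -> int:
    return sum(len(iv) for iv in intervals)


@dataclass
class GeneModel:
    """A protein-coding gene model with exact 5'UTR / ORF / 3'UTR partition.

    The three segment lists partition the exon bases exactly: every exon
    base falls in exactly one of ``utr5``, ``orf_exons`` or ``utr3``.
    The 3'UTR is 3' of the CDS *respecting strand*: for a minus-strand
    gene it lies at lower coordinates.  A gene with an empty CDS
    (``cds_start == cds_end``, the BED12 convention for non-coding
    transcripts) carries all its exon bases in ``utr3``.
    """

    id: str
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[GenomicInterval]
    cds_start: int
    cds_end: int
    utr5: list[GenomicInterval] = field(init=False)
    orf_exons: list[GenomicInterval] = field(init=False)
    utr3: list[GenomicInterval] = field(init=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be + or -")
        if self.cds_start > self.cds_end:
            raise ValueError(f"gene {self.id}: cds_start > cds_end")
        exons = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValueError(f"gene {self.id}: overlapping exon blocks")
        self.exons = exons
        self._segment()

    def _segment(self) -> None:
        left: list[GenomicInterval] = []   # exon bases < cds_start
        orf: list[GenomicInterval] = []
        right: list[GenomicInterval] = []  # exon bases >= cds_end
        coding = self.cds_start < self.cds_end
        for ex in self.exons:
            if not coding:
                right.append(ex)
                continue
            if ex.start < self.cds_start:
                left.append(
                    GenomicInterval(
                        self.chrom, ex.start, min(ex.end, self.cds_start), self.strand
                    )
                )
            lo = max(ex.start, self.cds_start)
            hi = min(ex.end, self.cds_end)
            if lo < hi:
                orf.append(GenomicInterval(self.chrom, lo, hi, self.strand))
            if ex.end > self.cds_end:
                right.append(
                    GenomicInterval(
                        self.chrom, max(ex.start, self.cds_end), ex.end, self.strand
                    )
                )
        if self.strand == "+":
            self.utr5, self.orf_exons, self.utr3 = left, orf, right
        else:
            self.utr5, self.orf_exons, self.utr3 = right, orf, left

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def utr3_span(self) -> GenomicInterval | None:
        """Envelope of the 3'UTR blocks (None for a gene with no 3'UTR)."""
        if not self.utr3:
            return None
        return GenomicInterval(
            self.chrom, self.utr3[0].start, self.utr3[-1].end, self.strand
        )

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate of the transcript 3' end (strand-aware)."""
        return self.end if self.strand == "+" else self.start
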