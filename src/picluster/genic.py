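"""Gene-centric piRNA cluster calling.

Reads are counted on the mRNA strand within the 5'UTR, ORF and 3'UTR
segments of each gene model.  UTRs are extended window-by-window
(2000 bp windows in mammals, 500 bp in Drosophilids) while each next
window carries at least 1 RPM of same-strand reads, bounded by the
nearest same-strand neighboring gene and a window cap.  A gene is
called a genic piC when its same-strand 3'UTR signal reaches 10 RPM
(20 RPM in the stringent mode); genes whose ORF alone carries >= 50 RPM
are flagged.  Automated curation filters reproduce the study's manual
grooming: transposon-dominated 3'UTRs, signal explained by a
neighboring gene, duplicate name entries, non-coding "Gm####"-style
identifiers and repetitive gene families.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

from .config import Thresholds
from .coverage import CoverageTrack
from .intervals import GeneModel, GenomicInterval

DEFAULT_NCRNA_PATTERNS = (r"^Gm\d+$",)
DEFAULT_FAMILY_BLACKLIST = ("Hist", "Olfr", "Zfp", "OR", "ZNF", "HIST")


@dataclass
class GeneCounts:
    gene: GeneModel
    utr5_count: float
    orf_count: float
    utr3_count: float
    library_size: int
    utr3_extension_bp: int = 0
    utr5_extension_bp: int = 0

    def _rpm(self, count: float) -> float:
        return count * 1e6 / self.library_size

    @property
    def utr5_rpm(self) -> float:
        return self._rpm(self.utr5_count)

    @property
    def orf_rpm(self) -> float:
        return self._rpm(self.orf_count)

    @property
    def utr3_rpm(self) -> float:
        return self._rpm(self.utr3_count)


@dataclass
class GenicPiC:
    counts: GeneCounts
    orf_retained: bool
    status: str = "kept"        # kept / removed
    reason: str = ""            # removal reason code

    @property
    def gene(self) -> GeneModel:
        return self.counts.gene

    @property
    def name(self) -> str:
        return self.counts.gene.name


def same_strand_neighbor_bound(gene: GeneModel, genes: list[GeneModel]) -> int | None:
    """Coordinate of the nearest same-strand gene in the 3' direction.

    Returns the coordinate extension must not cross, or None when there
    is no same-strand neighbor downstream of the transcript 3' end.
    """
    bound: int | None = None
    for other in genes:
        if other is gene or other.chrom != gene.chrom or other.strand != gene.strand:
            continue
        if gene.strand == "+":
            if other.start >= gene.end and (bound is None or other.start < bound):
                bound = other.start
        else:
            if other.end <= gene.start and (bound is None or other.end > bound):
                bound = other.end
    return bound


def extend_utr(
    gene: GeneModel,
    track_same_strand: CoverageTrack,
    window_bp: int,
    min_rpm: float = 1.0,
    max_windows: int = 5,
    neighbor_bound: int | None = None,
    chrom_size: int | None = None,
    which: str = "utr3",
) -> GenomicInterval | None:
    """Extend the annotated UTR window-by-window past the transcript end.

    Each candidate window of ``window_bp`` beyond the current end must
    hold >= ``min_rpm`` of same-strand reads for the extension to grow;
    the first failing window stops it.  Extension is clipped at the
    same-strand neighbor bound and the chromosome end (clipping is not
    an error), and capped at ``max_windows`` windows.

    Returns the extension interval, or None if no extension applied.
    """
    if which not in ("utr3", "utr5"):
        raise ValueError("which must be 'utr3' or 'utr5'")
    # Direction of growth: 3'UTR grows 3' of the transcript, 5'UTR 5' of it.
    grow_right = (gene.strand == "+") == (which == "utr3")
    anchor = (gene.end if grow_right else gene.start)

    ext_start = ext_end = anchor
    for _ in range(max_windows):
        if grow_right:
            w_start, w_end = ext_end, ext_end + window_bp
            if neighbor_bound is not None:
                w_end = min(w_end, neighbor_bound)
            if chrom_size is not None:
                w_end = min(w_end, chrom_size)
        else:
            w_start, w_end = ext_start - window_bp, ext_start
            if neighbor_bound is not None:
                w_start = max(w_start, neighbor_bound)
            w_start = max(w_start, 0)
        if w_start >= w_end:
            break
        rpm = track_same_strand.rpm(gene.chrom, w_start, w_end)
        if rpm < min_rpm:
            break
        ext_start, ext_end = min(ext_start, w_start), max(ext_end, w_end)
        if (grow_right and (w_end - anchor) % window_bp != 0) or (
            not grow_right and (anchor - w_start) % window_bp != 0
        ):
            break  # hit a clip bound; cannot grow further
    if ext_start == ext_end:
        return None
    return GenomicInterval(gene.chrom, ext_start, ext_end, gene.strand)


def count_gene_regions(
    gene: GeneModel,
    plus_track: CoverageTrack,
    minus_track: CoverageTrack,
    window_bp: int = 2000,
    extension_min_rpm: float = 1.0,
    max_windows: int = 5,
    neighbor_bound: int | None = None,
    chrom_size: int | None = None,
    extend: bool = True,
) -> GeneCounts:
    """Count reads on the mRNA strand in utr5 / ORF / utr3 (+ extension)."""
    track = plus_track if gene.strand == "+" else minus_track
    utr5_count = track.count_intervals(gene.utr5)
    orf_count = track.count_intervals(gene.orf_exons)
    utr3_count = track.count_intervals(gene.utr3)
    utr3_ext_bp = utr5_ext_bp = 0
    if extend:
        ext3 = extend_utr(
            gene, track, window_bp, extension_min_rpm, max_windows,
            neighbor_bound=neighbor_bound, chrom_size=chrom_size, which="utr3",
        )
        if ext3 is not None:
            utr3_count += track.count(ext3.chrom, ext3.start, ext3.end)
            utr3_ext_bp = len(ext3)
        # The 5'UTR extension is computed for reporting; it never enters
        # the retention decision, which cites only the 3'UTR.
        ext5 = extend_utr(
            gene, track, window_bp, extension_min_rpm, max_windows,
            chrom_size=chrom_size, which="utr5",
        )
        if ext5 is not None:
            utr5_count += track.count(ext5.chrom, ext5.start, ext5.end)
            utr5_ext_bp = len(ext5)
    return GeneCounts(
        gene, utr5_count, orf_count, utr3_count, track.library_size,
        utr3_extension_bp=utr3_ext_bp, utr5_extension_bp=utr5_ext_bp,
    )


def call_genic_pics(
    genes: list[GeneModel],
    plus_track: CoverageTrack,
    minus_track: CoverageTrack,
    thresholds: Thresholds | None = None,
    window_bp: int = 2000,
    chrom_sizes: dict[str, int] | None = None,
    extend: bool = True,
) -> list[GenicPiC]:
    """Call genic piCs: kept iff same-strand 3'UTR RPM >= genic_min_rpm.

    Output order is deterministic (chrom, start).  The ``orf_retained``
    flag marks genes whose ORF also carries >= orf_min_rpm.
    """
    th = thresholds or Thresholds()
    called: list[GenicPiC] = []
    for gene in sorted(genes, key=lambda g: (g.chrom, g.start, g.id)):
        bound = same_strand_neighbor_bound(gene, genes)
        size = chrom_sizes.get(gene.chrom) if chrom_sizes else None
        gc = count_gene_regions(
            gene, plus_track, minus_track, window_bp,
            th.extension_min_rpm, th.extension_max_windows,
            neighbor_bound=bound, chrom_size=size, extend=extend,
        )
        if gc.utr3_rpm >= th.genic_min_rpm:
            called.append(GenicPiC(gc, orf_retained=gc.orf_rpm >= th.orf_min_rpm))
    return called


@dataclass
class CurationResult:
    kept: list[GenicPiC]
    removed: list[GenicPiC] = field(default_factory=list)


def apply_curation_filters(
    candidates: list[GenicPiC],
    plus_track: CoverageTrack | None = None,
    minus_track: CoverageTrack | None = None,
    te_annotation: list[GenomicInterval] | None = None,
    all_genes: list[GeneModel] | None = None,
    ncrna_patterns: tuple[str, ...] = DEFAULT_NCRNA_PATTERNS,
    family_blacklist: tuple[str, ...] = DEFAULT_FAMILY_BLACKLIST,
    te_frac: float = 0.5,
    neighbor_frac: float = 0.5,
) -> CurationResult:
    """Automated reproduction of the candidate-grooming step.

    Removal reasons: ``TE_overlap`` (>= te_frac of 3'UTR piRNA signal
    inside annotated repeats), ``neighbor_gene_source`` (>= neighbor_frac
    of the signal lies within an overlapping/adjacent gene's own span),
    ``duplicate_name`` (lower-signal duplicate entries), ``ncRNA_pattern``
    and ``blacklist_family`` (name rules).
    """
    removed: list[GenicPiC] = []
    kept: list[GenicPiC] = []
    compiled = [re.compile(p, re.IGNORECASE) for p in ncrna_patterns]

    # duplicate names: keep the entry with the highest 3'UTR signal
    best_for_name: dict[str, GenicPiC] = {}
    for cand in candidates:
        cur = best_for_name.get(cand.name)
        if cur is None or cand.counts.utr3_count > cur.counts.utr3_count:
            best_for_name[cand.name] = cand

    for cand in candidates:
        gene = cand.gene
        if best_for_name[cand.name] is not cand:
            removed.append(_removed(cand, "duplicate_name"))
            continue
        if any(p.match(cand.name) for p in compiled):
            removed.append(_removed(cand, "ncRNA_pattern"))
            continue
        if any(cand.name.startswith(pref) for pref in family_blacklist):
            removed.append(_removed(cand, "blacklist_family"))
            continue
        track = None
        if plus_track is not None and minus_track is not None:
            track = plus_track if gene.strand == "+" else minus_track
        utr3_signal = (
            track.count_intervals(gene.utr3) if track is not None else 0.0
        )
        if te_annotation and track is not None and utr3_signal > 0:
            te_signal = 0.0
            for utr in gene.utr3:
                for rep in te_annotation:
                    if rep.chrom != utr.chrom:
                        continue
                    lo = max(utr.start, rep.start)
                    hi = min(utr.end, rep.end)
                    if lo < hi:
                        te_signal += track.count(utr.chrom, lo, hi)
            if te_signal / utr3_signal >= te_frac:
                removed.append(_removed(cand, "TE_overlap"))
                continue
        if all_genes and track is not None and utr3_signal > 0:
            explained = False
            span = gene.utr3_span
            for other in all_genes:
                if other.id == gene.id or other.chrom != gene.chrom:
                    continue
                if span is None or not span.overlaps(other.interval):
                    continue
                inside = track.count(
                    gene.chrom,
                    max(span.start, other.start),
                    min(span.end, other.end),
                )
                if inside / utr3_signal >= neighbor_frac:
                    explained = True
                    break
            if explained:
                removed.append(_removed(cand, "neighbor_gene_source"))
                continue
        kept.append(cand)
    return CurationResult(kept=kept, removed=removed)


def _removed(cand: GenicPiC, reason: str) -> GenicPiC:
    return GenicPiC(cand.counts, cand.orf_retained, status="removed", reason=reason)
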