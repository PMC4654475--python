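"""Sliding-window intergenic piRNA cluster calling and synteny anchoring.

The genome is tiled in 5 kb windows (step = window size, configurable).
A cluster initiates when a window's combined-strand signal exceeds
1 RPM and terminates at the first window below 1 RPM; contiguous
qualifying windows are merged and the cluster kept when its total
reaches 10 RPM.  Intergenic clusters are equated across species by the
ordered pair of reference-rooted names of their nearest flanking genes
(the synteny anchor).
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .coverage import CoverageTrack
from .intervals import GeneModel, GenomicInterval
from .io import OrthologMap, UNMAPPED

ANCHOR_NONE = "*"  # one-sided anchor sentinel


@dataclass
class SyntenyAnchor:
    upstream: str       # reference name of the nearest gene at lower coords
    downstream: str     # reference name of the nearest gene at higher coords
    one_sided: bool

    @property
    def key(self) -> str:
        return f"{self.upstream}|{self.downstream}"


@dataclass
class IntergenicPiC:
    interval: GenomicInterval
    total_rpm: float
    plus_rpm: float
    minus_rpm: float
    window_trace: list[float] = field(default_factory=list)
    anchor: SyntenyAnchor | None = None
    overlaps_genic: bool = False

    @property
    def name(self) -> str:
        return self.anchor.key if self.anchor else (
            f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
        )


def call_intergenic_pics(
    plus_track: CoverageTrack,
    minus_track: CoverageTrack,
    window_bp: int = 5000,
    start_rpm: float = 1.0,
    stop_rpm: float = 1.0,
    min_total_rpm: float = 10.0,
    chrom_sizes: dict[str, int] | None = None,
    genic_intervals: list[GenomicInterval] | None = None,
    genic_mode: str = "flag",
) -> list[IntergenicPiC]:
    """Call intergenic clusters as maximal runs of qualifying windows.

    A run starts at a window whose combined-strand RPM > ``start_rpm``
    and continues while windows hold >= ``stop_rpm``; the terminal
    partial window of a chromosome is included with its actual counts.
    Clusters totalling < ``min_total_rpm`` are dropped.  Clusters
    overlapping called genic piCs are flagged (``genic_mode='flag'``)
    or dropped (``'drop'``).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if genic_mode not in ("flag", "drop"):
        raise ValueError("genic_mode must be 'flag' or 'drop'")
    chroms = sorted(set(plus_track.chroms) | set(minus_track.chroms))
    clusters: list[IntergenicPiC] = []
    for chrom in chroms:
        size = None if chrom_sizes is None else chrom_sizes.get(chrom)
        if size is None:
            size = max(plus_track.max_position(chrom),
                       minus_track.max_position(chrom)) + 1
        run_windows: list[tuple[int, int, float, float]] = []
        start = 0
        while start < size:
            end = min(start + window_bp, size)
            p = plus_track.rpm(chrom, start, end)
            m = minus_track.rpm(chrom, start, end)
            rpm = p + m
            if not run_windows:
                if rpm > start_rpm:
                    run_windows.append((start, end, p, m))
            else:
                if rpm >= stop_rpm:
                    run_windows.append((start, end, p, m))
                else:
                    clusters.extend(
                        _finish_run(chrom, run_windows, min_total_rpm)
                    )
                    run_windows = []
                    # a terminating window may itself start a new cluster
                    if rpm > start_rpm:
                        run_windows.append((start, end, p, m))
            start = end
        if run_windows:
            clusters.extend(_finish_run(chrom, run_windows, min_total_rpm))

    if genic_intervals:
        flagged: list[IntergenicPiC] = []
        for cl in clusters:
            hit = any(cl.interval.overlaps(g) for g in genic_intervals)
            if hit and genic_mode == "drop":
                continue
            cl.overlaps_genic = hit
            flagged.append(cl)
        clusters = flagged
    return clusters


def _finish_run(
    chrom: str,
    windows: list[tuple[int, int, float, float]],
    min_total_rpm: float,
) -> list[IntergenicPiC]:
    plus = sum(w[2] for w in windows)
    minus = sum(w[3] for w in windows)
    total = plus + minus
    if total < min_total_rpm:
        return []
    return [
        IntergenicPiC(
            interval=GenomicInterval(chrom, windows[0][0], windows[-1][1]),
            total_rpm=total,
            plus_rpm=plus,
            minus_rpm=minus,
            window_trace=[w[2] + w[3] for w in windows],
        )
    ]


def anchor_by_synteny(
    cluster: IntergenicPiC,
    genes: list[GeneModel],
    ortholog_map: OrthologMap | None = None,
    species: str | None = None,
    max_anchor_dist: int = 1_000_000,
) -> SyntenyAnchor:
    """Anchor a cluster to its nearest non-overlapping flanking genes.

    The anchor key is the ordered (upstream, downstream) pair of
    reference-rooted names; clusters in different species with equal
    keys are declared syntenic orthologs.  A side with no gene within
    ``max_anchor_dist`` gets the one-sided sentinel.
    """
    iv = cluster.interval
    up_gene: GeneModel | None = None
    down_gene: GeneModel | None = None
    for g in genes:
        if g.chrom != iv.chrom or g.interval.overlaps(iv):
            continue
        if g.end <= iv.start:
            if iv.start - g.end <= max_anchor_dist and (
                up_gene is None or g.end > up_gene.end
            ):
                up_gene = g
        elif g.start >= iv.end:
            if g.start - iv.end <= max_anchor_dist and (
                down_gene is None or g.start < down_gene.start
            ):
                down_gene = g

    def ref_name(g: GeneModel | None) -> str:
        if g is None:
            return ANCHOR_NONE
        if ortholog_map is not None and species is not None:
            name = ortholog_map.lookup(species, g.id)
            return g.name if name == UNMAPPED else name
        return g.name

    up, down = ref_name(up_gene), ref_name(down_gene)
    return SyntenyAnchor(up, down, one_sided=(up == ANCHOR_NONE or down == ANCHOR_NONE))
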