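"""Conservation-score averaging, structural-element counting, controls.

Per-base phastCons/phyloP dumps are averaged over gene segments (sum of
scores divided by segment length); predicted structural elements
(provided as BED intervals by external predictors) are counted per ORF
and 3'UTR; negative-control genes are drawn from expressed genes that
produce no piRNAs, three per piC gene, with their 3'UTRs padded toward
the piC mean length within a clade-specific range (250-500 bp fly,
500-1100 bp mouse) unless the padding would run into a same-strand
neighbor.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import ScoreTrack
from .genic import same_strand_neighbor_bound
from .intervals import GeneModel, GenomicInterval, total_length


def interval_mean_score(
    track: ScoreTrack,
    intervals: list[GenomicInterval],
    missing: str = "zero",
) -> float:
    """Mean per-base score over intervals.

    ``missing='zero'`` counts bases absent from the track as 0 (the
    phastCons genome-dump convention); ``'exclude'`` averages over
    covered bases only (useful for phyloP).
    """
    if not intervals:
        raise ValueError("empty interval list")
    if missing not in ("zero", "exclude"):
        raise ValueError("missing must be 'zero' or 'exclude'")
    score_sum = sum(track.sum(iv.chrom, iv.start, iv.end) for iv in intervals)
    if missing == "zero":
        denom = total_length(intervals)
    else:
        denom = sum(track.covered(iv.chrom, iv.start, iv.end) for iv in intervals)
        if denom == 0:
            return float("nan")
    return score_sum / denom


def count_elements(
    elements: list[GenomicInterval],
    gene_sets: dict[str, list[GeneModel]],
) -> pd.DataFrame:
    """Mean number of elements overlapping ORF vs 3'UTR per gene set.

    An element spanning the ORF/3'UTR boundary is counted once per
    segment it overlaps.  Counting is independent of element order.
    """
    rows = []
    for set_name, genes in gene_sets.items():
        orf_counts = []
        utr3_counts = []
        for g in genes:
            orf_counts.append(
                sum(1 for e in elements if any(e.overlaps(iv) for iv in g.orf_exons))
            )
            utr3_counts.append(
                sum(1 for e in elements if any(e.overlaps(iv) for iv in g.utr3))
            )
        rows.append({
            "set": set_name,
            "n_genes": len(genes),
            "mean_orf_elements": float(np.mean(orf_counts)) if genes else float("nan"),
            "mean_utr3_elements": float(np.mean(utr3_counts)) if genes else float("nan"),
        })
    return pd.DataFrame(rows)


def compare_score_sets(scores_a: list[float], scores_b: list[float]) -> tuple[float, float]:
    """Mann-Whitney U comparison of two per-gene score lists."""
    stat, p = stats.mannwhitneyu(scores_a, scores_b, alternative="two-sided")
    return float(stat), float(p)


@dataclass
class ControlGene:
    gene: GeneModel
    padded_utr3: GenomicInterval | None
    pad_bp: int
    pad_truncated: bool


def select_negative_controls(
    genes: list[GeneModel],
    pic_genes: list[GeneModel],
    expressed: set[str] | None = None,
    multiplier: int = 3,
    pad_range: tuple[int, int] = (500, 1100),
    seed: int = 0,
) -> tuple[list[ControlGene], bool]:
    """Select length-matched non-piRNA control genes.

    Draws ``multiplier`` x |pic_genes| controls (seeded RNG) from
    expressed genes outside the piC set, padding each control 3'UTR
    within ``pad_range`` toward the mean piC 3'UTR length; padding is
    truncated at same-strand neighbors.  Returns (controls, complete):
    ``complete`` is False when the candidate pool was smaller than
    requested (all available are returned, flagged).
    """
    pic_ids = {g.id for g in pic_genes}
    pool = [
        g for g in genes
        if g.id not in pic_ids
        and g.utr3
        and (expressed is None or g.id in expressed or g.name in expressed)
    ]
    n_requested = multiplier * len(pic_genes)
    rng = np.random.default_rng(seed)
    complete = len(pool) >= n_requested
    if complete:
        idx = rng.choice(len(pool), size=n_requested, replace=False)
        chosen = [pool[i] for i in sorted(idx)]
    else:
        chosen = pool
    pic_mean = (
        float(np.mean([total_length(g.utr3) for g in pic_genes]))
        if pic_genes else 0.0
    )
    lo, hi = pad_range
    controls: list[ControlGene] = []
    for g in chosen:
        span = g.utr3_span
        current = total_length(g.utr3)
        want = int(np.clip(round(pic_mean - current), lo, hi))
        bound = same_strand_neighbor_bound(g, genes)
        truncated = False
        if g.strand == "+":
            pad_end = span.end + want
            if bound is not None and pad_end > bound:
                pad_end, truncated = bound, True
            pad = pad_end - span.end
            padded = (
                GenomicInterval(g.chrom, span.start, pad_end, g.strand)
                if pad_end > span.start else span
            )
        else:
            pad_start = span.start - want
            if bound is not None and pad_start < bound:
                pad_start, truncated = bound, True
            pad_start = max(0, pad_start)
            pad = span.start - pad_start
            padded = (
                GenomicInterval(g.chrom, pad_start, span.end, g.strand)
                if pad_start < span.end else span
            )
        controls.append(ControlGene(g, padded, int(pad), truncated))
    return controls, complete
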