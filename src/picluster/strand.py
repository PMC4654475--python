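"""Single-stranded configuration index of piRNA clusters.

For a 5 kb window with plus-strand RPM A and minus-strand RPM B the
index is (A - B)^2 / (A^2 + B^2): 1 when all signal is on one strand,
0 when the strands balance.  A cluster's index is the unweighted mean
over its 5 kb windows; windows with A = B = 0 are undefined and are
excluded from the mean (excluding rather than imputing 0 or 1 avoids
biasing the average either way; a config switch scores them 0 for
sensitivity probes).
"""
from __future__ import annotations

from dataclasses import dataclass

from .coverage import CoverageTrack
from .intervals import GenomicInterval


def window_index(a: float, b: float) -> float:
    """(A-B)^2 / (A^2+B^2) for one window; undefined at A=B=0."""
    if a < 0 or b < 0:
        raise ValueError("strand RPMs must be non-negative")
    if a == 0 and b == 0:
        raise ValueError("window index undefined for A=B=0")
    return (a - b) ** 2 / (a ** 2 + b ** 2)


@dataclass
class StrandIndexResult:
    index: float
    n_windows: int
    n_undefined: int


def cluster_strand_index(
    cluster: GenomicInterval,
    plus_track: CoverageTrack,
    minus_track: CoverageTrack,
    window_bp: int = 5000,
    include_partial: bool = True,
    zero_policy: str = "exclude",
) -> StrandIndexResult:
    """Mean window index over a cluster split into 5 kb windows.

    ``zero_policy='exclude'`` drops A=B=0 windows from the mean (their
    count is reported); ``'zero'`` scores them 0.  The terminal partial
    window is included by default (its RPMs are genuine).
    """
    if zero_policy not in ("exclude", "zero"):
        raise ValueError("zero_policy must be 'exclude' or 'zero'")
    values: list[float] = []
    n_undefined = 0
    n_windows = 0
    start = cluster.start
    while start < cluster.end:
        end = min(start + window_bp, cluster.end)
        if end - start < window_bp and not include_partial and n_windows > 0:
            break
        a = plus_track.rpm(cluster.chrom, start, end)
        b = minus_track.rpm(cluster.chrom, start, end)
        n_windows += 1
        if a == 0 and b == 0:
            n_undefined += 1
            if zero_policy == "zero":
                values.append(0.0)
        else:
            values.append(window_index(a, b))
        start = end
    if not values:
        raise ValueError("all windows undefined: empty cluster")
    return StrandIndexResult(sum(values) / len(values), n_windows, n_undefined)
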