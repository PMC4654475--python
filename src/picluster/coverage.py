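"""Sparse per-base tracks: read-start coverage and conservation scores.

A :class:`CoverageTrack` stores, for one strand of one library, the
number of reads starting at each covered base (configurable upstream to
full-cover pileup — the container is agnostic; it holds position ->
value).  Tracks are sparse: positions with zero signal are not stored.
RPM(x) = x * 1e6 / library_size, with the library size supplied from
the mapping manifest, never inferred from the (possibly strand-subset)
track itself.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .intervals import GenomicInterval


class TrackParseError(ValueError):
    """Raised when a coverage/score file cannot be parsed."""


class _SparseTrack:
    """Per-chromosome sorted position/value arrays with range-sum queries."""

    def __init__(self) -> None:
        self._pos: dict[str, np.ndarray] = {}
        self._val: dict[str, np.ndarray] = {}
        self._cum: dict[str, np.ndarray] = {}

    @classmethod
    def from_mapping(cls, data: dict[str, dict[int, float]]) -> "_SparseTrack":
        t = cls()
        for chrom, posmap in data.items():
            if posmap:
                pos = np.fromiter(posmap.keys(), dtype=np.int64, count=len(posmap))
                val = np.fromiter(posmap.values(), dtype=np.float64, count=len(posmap))
                order = np.argsort(pos, kind="stable")
                t._set(chrom, pos[order], val[order])
        return t

    def _set(self, chrom: str, pos: np.ndarray, val: np.ndarray) -> None:
        self._pos[chrom] = pos
        self._val[chrom] = val
        self._cum[chrom] = np.concatenate([[0.0], np.cumsum(val)])

    @property
    def chroms(self) -> list[str]:
        return sorted(self._pos)

    def max_position(self, chrom: str) -> int:
        if chrom not in self._pos or self._pos[chrom].size == 0:
            return 0
        return int(self._pos[chrom][-1])

    def range_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of values at positions in [start, end)."""
        if chrom not in self._pos:
            return 0.0
        pos, cum = self._pos[chrom], self._cum[chrom]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return float(cum[hi] - cum[lo])

    def range_covered(self, chrom: str, start: int, end: int) -> int:
        """Number of stored positions in [start, end)."""
        if chrom not in self._pos:
            return 0
        pos = self._pos[chrom]
        return int(
            np.searchsorted(pos, end, side="left")
            - np.searchsorted(pos, start, side="left")
        )

    def items(self, chrom: str) -> Iterator[tuple[int, float]]:
        if chrom in self._pos:
            yield from zip(self._pos[chrom].tolist(), self._val[chrom].tolist())

    def to_mapping(self) -> dict[str, dict[int, float]]:
        return {
            chrom: dict(self.items(chrom)) for chrom in self.chroms
        }


@dataclass
class CoverageTrack:
    """Strand-specific read counts per base for one library."""

    strand: str
    library_size: int
    assembly: str = "custom"
    _track: _SparseTrack = field(default_factory=_SparseTrack, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("CoverageTrack strand must be + or -")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")

    @classmethod
    def from_mapping(
        cls,
        data: dict[str, dict[int, float]],
        strand: str,
        library_size: int,
        assembly: str = "custom",
    ) -> "CoverageTrack":
        for chrom, posmap in data.items():
            for p, v in posmap.items():
                if v < 0:
                    raise ValueError(f"negative count at {chrom}:{p}")
        return cls(strand, library_size, assembly, _SparseTrack.from_mapping(data))

    @property
    def chroms(self) -> list[str]:
        return self._track.chroms

    def max_position(self, chrom: str) -> int:
        return self._track.max_position(chrom)

    def count(self, chrom: str, start: int, end: int) -> float:
        return self._track.range_sum(chrom, start, end)

    def count_intervals(self, intervals: Iterable[GenomicInterval]) -> float:
        return sum(self.count(iv.chrom, iv.start, iv.end) for iv in intervals)

    def rpm(self, chrom: str, start: int, end: int) -> float:
        return self.count(chrom, start, end) * 1e6 / self.library_size

    def rpm_intervals(self, intervals: Iterable[GenomicInterval]) -> float:
        return self.count_intervals(intervals) * 1e6 / self.library_size

    def to_mapping(self) -> dict[str, dict[int, float]]:
        return self._track.to_mapping()


@dataclass
class ScoreTrack:
    """Per-base float scores (e.g. phastCons in [0,1], phyloP unbounded)."""

    assembly: str = "custom"
    bounded_unit: bool = False  # enforce values in [0,1] (phastCons-style)
    _track: _SparseTrack = field(default_factory=_SparseTrack, repr=False)

    @classmethod
    def from_mapping(
        cls,
        data: dict[str, dict[int, float]],
        assembly: str = "custom",
        bounded_unit: bool = False,
    ) -> "ScoreTrack":
        if bounded_unit:
            for chrom, posmap in data.items():
                for p, v in posmap.items():
                    if not (0.0 <= v <= 1.0):
                        raise ValueError(f"score outside [0,1] at {chrom}:{p}")
        return cls(assembly, bounded_unit, _SparseTrack.from_mapping(data))

    def sum(self, chrom: str, start: int, end: int) -> float:
        return self._track.range_sum(chrom, start, end)

    def covered(self, chrom: str, start: int, end: int) -> int:
        return self._track.range_covered(chrom, start, end)


# ---------------------------------------------------------------------------
# bedGraph / WIG parsing and writing
# ---------------------------------------------------------------------------

def _parse_track_file(path: str) -> dict[str, dict[int, float]]:
    """Parse bedGraph or WIG (fixedStep/variableStep) into position->value.

    bedGraph is 0-based half-open; WIG is 1-based and shifted to 0-based
    on read.  ``span`` fields are honored.  Values at positions written
    more than once accumulate.
    """
    data: dict[str, dict[int, float]] = {}
    mode = "bedgraph"
    chrom = ""
    step = span = 1
    nextpos = 0

    def bump(c: str, p: int, v: float) -> None:
        if v < 0:
            raise TrackParseError(f"negative value at {c}:{p}")
        data.setdefault(c, {})
        data[c][p] = data[c].get(p, 0.0) + v

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(tok.split("=") for tok in line.split()[1:])
                mode, chrom = "fixed", kv["chrom"]
                nextpos = int(kv["start"]) - 1  # 1-based -> 0-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                continue
            if line.startswith("variableStep"):
                kv = dict(tok.split("=") for tok in line.split()[1:])
                mode, chrom = "variable", kv["chrom"]
                span = int(kv.get("span", 1))
                continue
            fields = line.split()
            try:
                if mode == "bedgraph" and len(fields) == 4:
                    c, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                    for p in range(s, e):
                        bump(c, p, v)
                elif mode == "fixed" and len(fields) == 1:
                    v = float(fields[0])
                    for p in range(nextpos, nextpos + span):
                        bump(chrom, p, v)
                    nextpos += step
                elif mode == "variable" and len(fields) == 2:
                    p0 = int(fields[0]) - 1
                    v = float(fields[1])
                    for p in range(p0, p0 + span):
                        bump(chrom, p, v)
                else:
                    raise ValueError("unexpected field count")
            except (ValueError, IndexError) as exc:
                if isinstance(exc, TrackParseError):
                    raise
                raise TrackParseError(f"{path}:{lineno}: cannot parse {line!r}") from exc
    return data


def read_coverage(path: str, strand: str, library_size: int,
                  assembly: str = "custom") -> CoverageTrack:
    """Read a bedGraph or WIG track as per-base read counts for one strand."""
    data = _parse_track_file(path)
    return CoverageTrack.from_mapping(data, strand, library_size, assembly)


def read_score_track(path: str, assembly: str = "custom",
                     bounded_unit: bool = False) -> ScoreTrack:
    """Read a bedGraph/WIG dump of per-base conservation scores."""
    data = _parse_track_file(path)
    return ScoreTrack.from_mapping(data, assembly, bounded_unit)


def write_bedgraph(data: dict[str, dict[int, float]], path: str) -> None:
    """Write a position->value map as bedGraph, merging equal-value runs."""
    with open(path, "w") as fh:
        for chrom in sorted(data):
            posmap = data[chrom]
            run_start = run_end = None
            run_val = 0.0
            for p in sorted(posmap):
                v = posmap[p]
                if v == 0:
                    continue
                if run_start is not None and p == run_end and v == run_val:
                    run_end += 1
                    continue
                if run_start is not None:
                    fh.write(f"{chrom}\t{run_start}\t{run_end}\t{_fmt(run_val)}\n")
                run_start, run_end, run_val = p, p + 1, v
            if run_start is not None:
                fh.write(f"{chrom}\t{run_start}\t{run_end}\t{_fmt(run_val)}\n")


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(v)
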