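"""Small-RNA library QC and expression normalization.

Read-length spectra (piRNA libraries show a main distribution of
23-32 nt; genuine piRNAs fall in 24-28 nt for Drosophilids and
24-31 nt for mammals), 5'-nucleotide composition (piRNAs carry a 5'
uridine bias), and the RPM -> RPKM -> housekeeping-ratio normalization
chain used for cross-species expression comparison.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass


@dataclass
class LengthSpectrum:
    counts: dict[int, int]
    window: tuple[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[int, float]:
        n = self.total
        return {length: c / n for length, c in sorted(self.counts.items())}

    @property
    def fraction_in_window(self) -> float:
        lo, hi = self.window
        inside = sum(c for length, c in self.counts.items() if lo <= length <= hi)
        return inside / self.total

    @property
    def mode(self) -> int:
        # deterministic tie-break: smallest length among maxima
        best = max(self.counts.values())
        return min(length for length, c in self.counts.items() if c == best)


def length_spectrum(reads: list[str], window: tuple[int, int] = (23, 32)) -> LengthSpectrum:
    """Histogram of read lengths with the declared piRNA window."""
    if not reads:
        raise ValueError("empty read set")
    counts = Counter(len(r) for r in reads)
    return LengthSpectrum(dict(counts), window)


def five_prime_composition(reads: list[str]) -> tuple[dict[str, float], int]:
    """Fractions of A/C/G/U at the 5' nucleotide; U and T are identical.

    Returns (fractions summing to 1, count of N-started reads excluded).
    """
    if not reads:
        raise ValueError("empty read set")
    counts = {"A": 0, "C": 0, "G": 0, "U": 0}
    n_excluded = 0
    for r in reads:
        base = r[0].upper()
        if base == "T":
            base = "U"
        if base in counts:
            counts[base] += 1
        else:
            n_excluded += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no reads with an unambiguous 5' nucleotide")
    return {b: c / total for b, c in counts.items()}, n_excluded


@dataclass
class ExpressionRecord:
    gene: str
    count: float
    rpm: float
    rpkm: float
    normalized: float | None  # RPKM / RPKM(housekeeping), None if not requested


def normalize(
    gene: str,
    count: float,
    library_size: int,
    length_bp: int,
    housekeeping_rpkm: float | None = None,
) -> ExpressionRecord:
    """RPM = count*1e6/library_size; RPKM = RPM*1e3/length; ratio to housekeeping."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    rpm = count * 1e6 / library_size
    rpkm = rpm * 1e3 / length_bp
    normalized = None
    if housekeeping_rpkm is not None:
        if housekeeping_rpkm <= 0:
            raise ValueError("housekeeping RPKM must be positive to normalize")
        normalized = rpkm / housekeeping_rpkm
    return ExpressionRecord(gene, count, rpm, rpkm, normalized)
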