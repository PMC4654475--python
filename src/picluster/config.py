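"""Clade presets and pipeline thresholds.

The defaults encode the analysis conditions of the comparative study:
UTR extension windows of 2000 bp for mammals and 500 bp for
Drosophilids, piRNA length windows of 24-31 nt (mammal) and 24-28 nt
(fly) with a 23-32 nt library-QC window, a 10 RPM 3'UTR retention
threshold (20 RPM in the stringent mode), a 50 RPM ORF flag, and the
5 kb intergenic sliding window with 1 RPM start/stop and 10 RPM total.
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CladePreset:
    name: str
    utr_extension_bp: int
    pirna_len: tuple[int, int]
    qc_len: tuple[int, int]
    control_pad_range: tuple[int, int]
    housekeeping_gene: str


CLADE_PRESETS: dict[str, CladePreset] = {
    "mammal": CladePreset(
        name="mammal",
        utr_extension_bp=2000,
        pirna_len=(24, 31),
        qc_len=(23, 32),
        control_pad_range=(500, 1100),
        housekeeping_gene="RpL32",
    ),
    "fly": CladePreset(
        name="fly",
        utr_extension_bp=500,
        pirna_len=(24, 28),
        qc_len=(23, 32),
        control_pad_range=(250, 500),
        housekeeping_gene="RpL32",  # Rp49 in older fly nomenclature
    ),
}


@dataclass
class Thresholds:
    """All tunable cutoffs of the pipeline, with study defaults."""

    genic_min_rpm: float = 10.0
    orf_min_rpm: float = 50.0
    extension_min_rpm: float = 1.0
    extension_max_windows: int = 5
    intergenic_window_bp: int = 5000
    intergenic_start_rpm: float = 1.0
    intergenic_stop_rpm: float = 1.0
    intergenic_min_total_rpm: float = 10.0
    strand_window_bp: int = 5000
    overlap_min_rpm: float = 10.0
    expr_pair_delta: float = 0.5     # |log10 x - log10 y| for 2 species
    expr_triple_sd: float = 0.3      # SD of log10 values for 3 species
    te_frac: float = 0.5
    neighbor_frac: float = 0.5
    max_anchor_dist: int = 1_000_000

    def __post_init__(self) -> None:
        for name in (
            "genic_min_rpm", "orf_min_rpm", "extension_min_rpm",
            "intergenic_window_bp", "intergenic_start_rpm",
            "intergenic_stop_rpm", "intergenic_min_total_rpm",
            "strand_window_bp", "overlap_min_rpm",
            "expr_pair_delta", "expr_triple_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def stringent(cls) -> "Thresholds":
        """Two-fold stricter overlap mode: 20 RPM, delta 0.3, SD 0.177."""
        return cls(
            overlap_min_rpm=20.0, expr_pair_delta=0.3, expr_triple_sd=0.177
        )
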