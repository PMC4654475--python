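"""End-to-end orchestration: call -> compare -> classify -> gain/loss.

Thin glue over the stage modules, used by the command-line interface
and by reproducibility scripts.  Operates on an in-memory simulated
bundle or on files loaded through :mod:`picluster.io`.
"""
from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd

from .config import CLADE_PRESETS, Thresholds
from .crossspecies import ConservationCall, build_repertoire_table, classify_conservation
from .gainloss import ParsimonyResult, branch_rates, presence_matrix, wagner_parsimony
from .genic import GenicPiC, call_genic_pics
from .intergenic import IntergenicPiC, anchor_by_synteny, call_intergenic_pics
from .io import UNMAPPED
from .simulate import SimulatedBundle
from .strand import StrandIndexResult, cluster_strand_index


@dataclass
class SpeciesCalls:
    species: str
    genic: list[GenicPiC]
    intergenic: list[IntergenicPiC]
    strand_indexes: list[StrandIndexResult]


@dataclass
class PipelineResult:
    calls: dict[str, SpeciesCalls]
    repertoire: pd.DataFrame
    conservation: list[ConservationCall]
    parsimony: ParsimonyResult
    rates: pd.DataFrame

    @property
    def labels(self) -> dict[str, str]:
        return {c.locus: c.label for c in self.conservation}


def run_bundle(
    bundle: SimulatedBundle,
    thresholds: Thresholds | None = None,
    clade: str = "mammal",
) -> PipelineResult:
    """Run the full comparative pipeline on a simulated bundle."""
    th = thresholds or Thresholds()
    preset = CLADE_PRESETS[clade]
    cfg = bundle.config
    calls: dict[str, SpeciesCalls] = {}
    per_species_rpm: dict[str, dict[str, float]] = {}

    for sp in cfg.species:
        ss = bundle.per_species[sp]
        genic = call_genic_pics(
            ss.genes, ss.plus, ss.minus, th,
            window_bp=preset.utr_extension_bp, chrom_sizes=ss.chrom_sizes,
        )
        genic_spans = [g.gene.interval for g in genic]
        intergenic = call_intergenic_pics(
            ss.plus, ss.minus,
            window_bp=th.intergenic_window_bp,
            start_rpm=th.intergenic_start_rpm,
            stop_rpm=th.intergenic_stop_rpm,
            min_total_rpm=th.intergenic_min_total_rpm,
            chrom_sizes=ss.chrom_sizes,
            genic_intervals=genic_spans,
            genic_mode="drop",
        )
        sidx = []
        for cl in intergenic:
            cl.anchor = anchor_by_synteny(
                cl, ss.genes, bundle.orthologs, sp, th.max_anchor_dist
            )
            sidx.append(cluster_strand_index(
                cl.interval, ss.plus, ss.minus, th.strand_window_bp
            ))
        calls[sp] = SpeciesCalls(sp, genic, intergenic, sidx)
        rpm_map: dict[str, float] = {}
        for g in genic:
            ref = bundle.orthologs.lookup(sp, g.gene.id)
            name = g.name if ref == UNMAPPED else ref
            rpm_map[name] = max(rpm_map.get(name, 0.0), g.counts.utr3_rpm)
        per_species_rpm[sp] = rpm_map

    repertoire = build_repertoire_table(per_species_rpm)
    conservation = classify_conservation(
        repertoire, cfg.clade_map, min_rpm=th.overlap_min_rpm
    )
    tree = dendropy.Tree.get(data=cfg.tree_newick, schema="newick")
    tree.is_rooted = True
    pm = presence_matrix(repertoire, min_rpm=th.overlap_min_rpm)
    parsimony = wagner_parsimony(tree, pm)
    rates = branch_rates(parsimony, n_characters=pm.shape[0])
    return PipelineResult(calls, repertoire, conservation, parsimony, rates)
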