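"""Synthetic multi-species piRNA scenario generation with known ground truth.

The generator emulates the study's sequencing conditions: per species a
gene annotation (BED12), strand-specific 5'-end read coverage
(bedGraph), the reads themselves (FASTA, piRNA-length 23-32 nt with a
configurable modal length and 5'U bias), and an mRNA expression table;
plus a shared ortholog table, a dated species tree and a library
manifest.  Designated genic piC genes receive Poisson-placed reads in
their 3'UTRs at a target RPM (default 50, well above the 10 RPM call
threshold); all other genes receive faint background (default
0.2 RPM).  Intergenic clusters are planted in gene-free territory with
single- or dual-strand read configurations.  Conservation patterns are
planted as explicit gain/loss events on tree branches, so cluster
calling, conservation classification and parsimony reconstruction can
all be checked against constructed truth.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .coverage import CoverageTrack, write_bedgraph
from .intervals import GeneModel, GenomicInterval
from .io import OrthologMap, write_bed12, write_ortholog_table
from .targets import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# gene template (coordinates relative to the gene start)
_GENE_SPAN = 4200
_GENE_PITCH = 10_000
_CLUSTER_GAP = 20_000


@dataclass
class ScenarioConfig:
    species: list[str]
    clade_map: dict[str, str]
    tree_newick: str
    genes_per_species: int = 200
    n_genic_pics: int = 20
    pic_target_rpm: float = 50.0
    background_rpm: float = 0.2
    n_intergenic: int = 8
    intergenic_labels: list[str] | None = None  # "single"/"dual" per cluster
    intergenic_window_rpm: float = 40.0
    intergenic_windows_per_cluster: int = 3
    length_range: tuple[int, int] = (23, 32)
    length_mode: int = 29
    u_bias: float = 0.8
    library_size: int = 2_000_000
    housekeeping_gene: str = "RpL32"
    expression_noise_sd: float = 0.05  # log10 units, cross-species
    # planted conservation pattern (counts must sum to <= n_genic_pics)
    n_conserved: int | None = None        # present in every species
    n_clade_specific: int = 0             # present in one clade only
    n_species_specific: int = 0           # gained on one terminal branch
    n_loss: int = 0                       # ancestral, lost in one species
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conserved is None:
            self.n_conserved = (
                self.n_genic_pics - self.n_clade_specific
                - self.n_species_specific - self.n_loss
            )
        planted = (
            self.n_conserved + self.n_clade_specific
            + self.n_species_specific + self.n_loss
        )
        if planted > self.genes_per_species:
            raise ValueError("more designated piC loci than genes")
        if self.n_conserved < 0:
            raise ValueError("conservation pattern exceeds n_genic_pics")
        if self.intergenic_labels is None:
            self.intergenic_labels = [
                "single" if i % 2 == 0 else "dual" for i in range(self.n_intergenic)
            ]
        if len(self.intergenic_labels) != self.n_intergenic:
            raise ValueError("intergenic_labels length mismatch")
        lo, hi = self.length_range
        if not (lo <= self.length_mode <= hi):
            raise ValueError("length_mode outside length_range")

    @classmethod
    def default(cls, seed: int = 0, **overrides) -> "ScenarioConfig":
        """Five species in three clades, 200 genes each, 20 shared piCs."""
        species = ["sp1", "sp2", "sp3", "sp4", "sp5"]
        clade_map = {"sp1": "A", "sp2": "A", "sp3": "B", "sp4": "B", "sp5": "C"}
        tree = "(((sp1:10,sp2:10):20,(sp3:10,sp4:10):20):30,sp5:60);"
        return cls(species=species, clade_map=clade_map, tree_newick=tree,
                   seed=seed, **overrides)

    @classmethod
    def eutherian_like(cls, seed: int = 0, **overrides) -> "ScenarioConfig":
        """Nine species in three clades mirroring Primates/Glires/Laurasiatherians."""
        species = [f"{c}{i}" for c in "PGL" for i in (1, 2, 3)]
        clade_map = {sp: {"P": "Primates", "G": "Glires",
                          "L": "Laurasiatherians"}[sp[0]] for sp in species}
        tree = (
            "((((P1:20,P2:20):20,P3:40):60,((G1:20,G2:20):20,G3:40):60):40,"
            "((L1:20,L2:20):20,L3:40):100);"
        )
        overrides.setdefault("n_clade_specific", 3)
        overrides.setdefault("n_species_specific", 3)
        overrides.setdefault("n_loss", 2)
        return cls(species=species, clade_map=clade_map, tree_newick=tree,
                   seed=seed, **overrides)


@dataclass
class PlantedLocus:
    ref_name: str
    gene_index: int
    pattern: str                           # conserved / clade / species / loss
    presence: dict[str, bool]
    #: planted events as (leafset below the branch, "gain"/"loss")
    events: list[tuple[frozenset, str]]


@dataclass
class GroundTruth:
    species: list[str]
    chrom_sizes: dict[str, dict[str, int]]
    #: per species: local ids of designated genic piC genes
    genic: dict[str, list[str]]
    #: per species: (interval, strand label) of planted intergenic clusters
    intergenic: dict[str, list[tuple[GenomicInterval, str]]]
    planted_loci: list[PlantedLocus]
    conservation_labels: dict[str, str]    # ref name -> ECpiC / LCpiC

    def to_json(self, path: str | Path) -> None:
        payload = {
            "species": self.species,
            "chrom_sizes": self.chrom_sizes,
            "genic": self.genic,
            "intergenic": {
                sp: [
                    {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                     "label": label}
                    for iv, label in items
                ]
                for sp, items in self.intergenic.items()
            },
            "planted_loci": [
                {**asdict(p), "events": [[sorted(ls), kind] for ls, kind in p.events]}
                for p in self.planted_loci
            ],
            "conservation_labels": self.conservation_labels,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SimulatedSpecies:
    species: str
    genes: list[GeneModel]
    plus: CoverageTrack
    minus: CoverageTrack
    reads: list[tuple[str, str]]
    expression: pd.Series
    chrom_sizes: dict[str, int]


@dataclass
class SimulatedBundle:
    config: ScenarioConfig
    per_species: dict[str, SimulatedSpecies]
    orthologs: OrthologMap
    truth: GroundTruth
    paths: dict[str, dict[str, str]] = field(default_factory=dict)


def _ref_name(i: int) -> str:
    return f"GENE{i:04d}"


def _make_genes(species: str, n: int) -> list[GeneModel]:
    genes = []
    for i in range(n):
        s = i * _GENE_PITCH
        strand = "+" if i % 2 == 0 else "-"
        exons = [
            GenomicInterval("chr1", s, s + 2000, strand),
            GenomicInterval("chr1", s + 2200, s + _GENE_SPAN, strand),
        ]
        if strand == "+":
            cds_start, cds_end = s + 200, s + 2400
        else:
            cds_start, cds_end = s + 1800, s + 4000
        genes.append(GeneModel(
            id=f"{species}_g{i:04d}", name=f"{species}_g{i:04d}",
            chrom="chr1", start=s, end=s + _GENE_SPAN, strand=strand,
            exons=exons, cds_start=cds_start, cds_end=cds_end,
        ))
    return genes


def _sample_lengths(rng: np.random.Generator, n: int,
                    length_range: tuple[int, int], mode: int) -> np.ndarray:
    lo, hi = length_range
    lengths = np.arange(lo, hi + 1)
    weights = 0.55 ** np.abs(lengths - mode)
    weights /= weights.sum()
    return rng.choice(lengths, size=n, p=weights)


def plant_conservation_pattern(
    config: ScenarioConfig, tree: dendropy.Tree, rng: np.random.Generator
) -> list[PlantedLocus]:
    """Assign piC loci to ancestral presence plus branch gain/loss events.

    Leaf presence is derived by propagating the events down the tree;
    conserved-by-construction loci are present in every species (hence
    in >= 1 species of every clade).
    """
    species = config.species
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    if set(leaves) != set(species):
        raise ValueError("tree leaves must equal the species list")

    n_total = (config.n_conserved + config.n_clade_specific
               + config.n_species_specific + config.n_loss)
    gene_indices = rng.choice(config.genes_per_species, size=n_total, replace=False)
    gene_indices = np.sort(gene_indices)

    def leafset_below(node: dendropy.Node) -> frozenset:
        return frozenset(l.taxon.label for l in node.leaf_iter())

    clades: dict[str, list[str]] = {}
    for sp in species:
        clades.setdefault(config.clade_map[sp], []).append(sp)
    clade_names = sorted(clades)

    planted: list[PlantedLocus] = []
    k = 0
    for _ in range(config.n_conserved):
        idx = int(gene_indices[k]); k += 1
        planted.append(PlantedLocus(
            _ref_name(idx), idx, "conserved",
            presence={sp: True for sp in species}, events=[],
        ))
    for j in range(config.n_clade_specific):
        idx = int(gene_indices[k]); k += 1
        clade = clade_names[j % len(clade_names)]
        members = set(clades[clade])
        mrca = tree.mrca(taxa=[leaves[sp].taxon for sp in members])
        if leafset_below(mrca) == frozenset(members) and mrca is not tree.seed_node:
            events = [(frozenset(members), "gain")]
        else:  # clade not monophyletic: gain on each terminal branch
            events = [(frozenset([sp]), "gain") for sp in sorted(members)]
        planted.append(PlantedLocus(
            _ref_name(idx), idx, "clade",
            presence={sp: sp in members for sp in species}, events=events,
        ))
    for j in range(config.n_species_specific):
        idx = int(gene_indices[k]); k += 1
        sp = species[j % len(species)]
        planted.append(PlantedLocus(
            _ref_name(idx), idx, "species",
            presence={s: s == sp for s in species},
            events=[(frozenset([sp]), "gain")],
        ))
    for j in range(config.n_loss):
        idx = int(gene_indices[k]); k += 1
        sp = species[(j + 1) % len(species)]
        planted.append(PlantedLocus(
            _ref_name(idx), idx, "loss",
            presence={s: s != sp for s in species},
            events=[(frozenset([sp]), "loss")],
        ))
    return planted


def conservation_label(presence: dict[str, bool],
                       clade_map: dict[str, str],
                       min_species_per_clade: int = 1) -> str:
    clades: dict[str, int] = {}
    totals: dict[str, int] = {}
    for sp, clade in clade_map.items():
        totals[clade] = totals.get(clade, 0) + 1
        clades[clade] = clades.get(clade, 0) + int(presence.get(sp, False))
    return (
        "ECpiC"
        if all(n >= min_species_per_clade for n in clades.values())
        else "LCpiC"
    )


def _place_reads_in_intervals(
    rng: np.random.Generator,
    intervals: list[GenomicInterval],
    n_reads: int,
) -> np.ndarray:
    """Uniform 5'-end positions over the bases of the given intervals."""
    lengths = np.array([len(iv) for iv in intervals])
    offsets = rng.integers(0, lengths.sum(), size=n_reads)
    starts = np.array([iv.start for iv in intervals])
    cum = np.concatenate([[0], np.cumsum(lengths)])
    which = np.searchsorted(cum, offsets, side="right") - 1
    return starts[which] + (offsets - cum[which])


def simulate_scenario(
    config: ScenarioConfig, outdir: str | Path | None = None
) -> tuple[SimulatedBundle, GroundTruth]:
    """Generate the full multi-species bundle; optionally write it to disk.

    Deterministic: the same config (including seed) yields an identical
    bundle and byte-identical files.
    """
    tree = dendropy.Tree.get(data=config.tree_newick, schema="newick")
    tree.is_rooted = True
    master_rng = np.random.default_rng(config.seed)
    planted = plant_conservation_pattern(config, tree, master_rng)
    labels = {
        p.ref_name: conservation_label(p.presence, config.clade_map)
        for p in planted
    }

    n_genes = config.genes_per_species
    cluster_span = config.intergenic_windows_per_cluster * 5000
    cluster_region = n_genes * _GENE_PITCH + _GENE_PITCH
    chrom_size = (
        cluster_region
        + config.n_intergenic * (cluster_span + _CLUSTER_GAP)
        + _GENE_PITCH
    )

    orthologs = OrthologMap()
    per_species: dict[str, SimulatedSpecies] = {}
    truth_genic: dict[str, list[str]] = {}
    truth_intergenic: dict[str, list[tuple[GenomicInterval, str]]] = {}
    chrom_sizes_all: dict[str, dict[str, int]] = {}

    # per-reference-gene baseline mRNA level, shared across species
    expr_rng = np.random.default_rng([config.seed, 7])
    base_expr = 10 ** expr_rng.uniform(1.5, 2.7, size=n_genes)

    for sp_i, sp in enumerate(config.species):
        rng = np.random.default_rng([config.seed, 101 + sp_i])
        genes = _make_genes(sp, n_genes)
        genome = rng.choice(_BASES, size=chrom_size)
        for i in range(n_genes):
            orthologs.add(sp, genes[i].id, _ref_name(i))

        plus: dict[int, float] = {}
        minus: dict[int, float] = {}
        reads: list[tuple[str, str]] = []
        read_no = 0

        def emit(pos5: np.ndarray, strand: str, tag: str) -> None:
            nonlocal read_no
            target = plus if strand == "+" else minus
            lengths = _sample_lengths(
                rng, len(pos5), config.length_range, config.length_mode
            )
            first = np.where(
                rng.random(len(pos5)) < config.u_bias,
                np.uint8(ord("T")),
                _BASES[[0, 1, 2]][rng.integers(0, 3, size=len(pos5))],
            )
            for p, L, fb in zip(pos5.tolist(), lengths.tolist(), first.tolist()):
                target[p] = target.get(p, 0.0) + 1
                if strand == "+":
                    seq = genome[p:p + L].tobytes().decode()
                else:
                    lo = max(0, p - L + 1)
                    seq = revcomp(genome[lo:p + 1].tobytes().decode())
                seq = chr(fb) + seq[1:]
                reads.append((f"{sp}_r{read_no:06d}_{tag}", seq))
                read_no += 1

        # designated genic piC reads
        designated: list[str] = []
        planted_by_idx = {p.gene_index: p for p in planted}
        for i, gene in enumerate(genes):
            p = planted_by_idx.get(i)
            if p is not None and p.presence[sp]:
                designated.append(gene.id)
                lam = config.pic_target_rpm * config.library_size / 1e6
            else:
                lam = config.background_rpm * config.library_size / 1e6
            n_reads = int(rng.poisson(lam))
            if n_reads:
                pos = _place_reads_in_intervals(rng, gene.utr3, n_reads)
                emit(np.sort(pos), gene.strand, f"g{i:04d}")

        # intergenic clusters
        clusters: list[tuple[GenomicInterval, str]] = []
        lam_win = config.intergenic_window_rpm * config.library_size / 1e6
        for j, label in enumerate(config.intergenic_labels):
            start = cluster_region + j * (cluster_span + _CLUSTER_GAP)
            iv = GenomicInterval("chr1", start, start + cluster_span)
            clusters.append((iv, label))
            main_strand = "+" if j % 2 == 0 else "-"
            for w in range(config.intergenic_windows_per_cluster):
                w_iv = GenomicInterval("chr1", start + w * 5000, start + (w + 1) * 5000)
                n_reads = int(rng.poisson(lam_win))
                if not n_reads:
                    continue
                pos = np.sort(_place_reads_in_intervals(rng, [w_iv], n_reads))
                if label == "single":
                    emit(pos, main_strand, f"ic{j}")
                else:
                    on_plus = rng.random(n_reads) < 0.5
                    emit(pos[on_plus], "+", f"ic{j}")
                    emit(pos[~on_plus], "-", f"ic{j}")

        plus_track = CoverageTrack.from_mapping(
            {"chr1": plus}, "+", config.library_size, assembly=sp
        )
        minus_track = CoverageTrack.from_mapping(
            {"chr1": minus}, "-", config.library_size, assembly=sp
        )

        noise = 10 ** rng.normal(0.0, config.expression_noise_sd, size=n_genes)
        expr = pd.Series(
            base_expr * noise, index=[g.id for g in genes]
        )
        expr[config.housekeeping_gene] = 500.0

        per_species[sp] = SimulatedSpecies(
            sp, genes, plus_track, minus_track, reads, expr,
            {"chr1": chrom_size},
        )
        truth_genic[sp] = designated
        truth_intergenic[sp] = clusters
        chrom_sizes_all[sp] = {"chr1": chrom_size}

    truth = GroundTruth(
        species=list(config.species),
        chrom_sizes=chrom_sizes_all,
        genic=truth_genic,
        intergenic=truth_intergenic,
        planted_loci=planted,
        conservation_labels=labels,
    )
    bundle = SimulatedBundle(config, per_species, orthologs, truth)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest_rows = []
        for sp in config.species:
            ss = per_species[sp]
            paths = {
                "genes": str(outdir / f"{sp}.genes.bed"),
                "plus": str(outdir / f"{sp}.plus.bedgraph"),
                "minus": str(outdir / f"{sp}.minus.bedgraph"),
                "reads": str(outdir / f"{sp}.reads.fasta"),
                "expression": str(outdir / f"{sp}.expression.tsv"),
            }
            write_bed12(ss.genes, paths["genes"])
            write_bedgraph(ss.plus.to_mapping(), paths["plus"])
            write_bedgraph(ss.minus.to_mapping(), paths["minus"])
            with open(paths["reads"], "w") as fh:
                for rid, seq in ss.reads:
                    fh.write(f">{rid}\n{seq}\n")
            pd.DataFrame(
                {"gene": ss.expression.index, "rpkm": ss.expression.values}
            ).to_csv(paths["expression"], sep="\t", index=False)
            manifest_rows.append({
                "library": sp, "species": sp,
                "library_size": config.library_size,
                # names relative to the bundle dir keep the manifest portable
                **{k: Path(v).name for k, v in paths.items()},
            })
            bundle.paths[sp] = paths
        write_ortholog_table(orthologs, outdir / "orthologs.tsv")
        (outdir / "tree.nwk").write_text(config.tree_newick + "\n")
        pd.DataFrame(manifest_rows).to_csv(
            outdir / "manifest.tsv", sep="\t", index=False
        )
        truth.to_json(outdir / "ground_truth.json")
    return bundle, truth


def make_target_transcripts(
    pirnas: list[tuple[str, str]],
    n_decoys: int = 10,
    transcript_len: int = 300,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Build transcripts embedding antisense matches to the given piRNAs.

    Each piRNA gets one target transcript carrying its exact reverse
    complement at a random position; ``n_decoys`` random transcripts
    carry no planted match.  Used for target-search recovery tests.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[str, str]] = []
    for i, (pid, seq) in enumerate(pirnas):
        insert = revcomp(seq)
        bg = rng.choice(_BASES, size=transcript_len).tobytes().decode()
        pos = int(rng.integers(0, transcript_len - len(insert)))
        out.append((f"target_{pid}", bg[:pos] + insert + bg[pos + len(insert):]))
    for j in range(n_decoys):
        out.append((
            f"decoy_{j}",
            rng.choice(_BASES, size=transcript_len).tobytes().decode(),
        ))
    return out
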