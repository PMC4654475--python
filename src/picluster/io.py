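"""Readers and writers for the external formats the pipeline touches.

BED12 gene models, ortholog tables, Newick trees, expression tables,
library manifests and FASTA/FASTQ small-RNA reads.  Coverage tracks
(bedGraph/WIG) live in :mod:`picluster.coverage`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import pandas as pd
from Bio import SeqIO

from .intervals import GenomicInterval, GeneModel

#: Sentinel returned by :meth:`OrthologMap.lookup` for genes without a
#: reference-rooted name.  Never silently the empty string.
UNMAPPED = "<unmapped>"


class BedParseError(ValueError):
    pass


def read_bed12(path: str) -> list[GeneModel]:
    """Parse a 12-column BED file into gene models.

    Records with ``thickStart > thickEnd`` are rejected with a warning;
    any other malformed line raises :class:`BedParseError` naming the
    line number.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise BedParseError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                strand = fields[5]
                cds_start, cds_end = int(fields[6]), int(fields[7])
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise BedParseError(f"{path}:{lineno}: blockCount mismatch")
            if cds_start > cds_end:
                warnings.warn(f"{path}:{lineno}: thickStart > thickEnd, record skipped")
                continue
            exons = [
                GenomicInterval(chrom, start + s, start + s + sz, strand)
                for s, sz in zip(starts, sizes)
            ]
            genes.append(
                GeneModel(
                    id=name, name=name, chrom=chrom, start=start, end=end,
                    strand=strand, exons=exons, cds_start=cds_start, cds_end=cds_end,
                )
            )
    return genes


def write_bed12(genes: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(len(e)) for e in g.exons)
            starts = ",".join(str(e.start - g.start) for e in g.exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\t"
                f"{g.cds_start}\t{g.cds_end}\t0\t{len(g.exons)}\t{sizes},\t{starts},\n"
            )


@dataclass
class OrthologMap:
    """(species, local gene id) -> reference-rooted gene name.

    The reference namespace is the best-annotated model organism for the
    clade (D. melanogaster for flies; human/mouse for mammals and
    chicken), so loci can be equated across species by name.
    """

    _table: dict[tuple[str, str], str] = field(default_factory=dict)

    def add(self, species: str, gene_id: str, ref_name: str) -> None:
        key = (species, gene_id)
        if key in self._table and self._table[key] != ref_name:
            raise ValueError(f"conflicting mapping for {key}")
        self._table[key] = ref_name

    def lookup(self, species: str, gene_id: str) -> str:
        """Return the reference name, or the UNMAPPED sentinel."""
        return self._table.get((species, gene_id), UNMAPPED)

    def species(self) -> list[str]:
        return sorted({sp for sp, _ in self._table})

    def __len__(self) -> int:
        return len(self._table)


def read_ortholog_table(path: str) -> OrthologMap:
    """Read a TSV with columns species, gene_id, ref_name (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"species", "gene_id", "ref_name"}
    if not required.issubset(df.columns):
        raise ValueError(f"ortholog table needs columns {sorted(required)}")
    omap = OrthologMap()
    for row in df.itertuples(index=False):
        omap.add(row.species, row.gene_id, row.ref_name)
    return omap


def write_ortholog_table(omap: OrthologMap, path: str) -> None:
    rows = [
        {"species": sp, "gene_id": gid, "ref_name": name}
        for (sp, gid), name in sorted(omap._table.items())
    ]
    pd.DataFrame(rows, columns=["species", "gene_id", "ref_name"]).to_csv(
        path, sep="\t", index=False
    )


def read_newick(path: str) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths in million years.

    Raises on duplicate leaf names or non-positive branch lengths.
    """
    try:
        tree = dendropy.Tree.get(path=path, schema="newick")
    except Exception as exc:
        if "uplicate" in str(exc):
            raise ValueError(f"duplicate leaf names in {path}") from exc
        raise
    tree.is_rooted = True
    names = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(names) != len(set(names)):
        raise ValueError("duplicate leaf names in tree")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None or edge.length <= 0:
            raise ValueError("all branch lengths must be > 0")
    return tree


def read_expression_table(path: str) -> pd.Series:
    """Read a two-column TSV gene -> expression value (header required)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("expression table needs >= 2 columns")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].astype(str).values)


def write_expression_table(values: pd.Series, path: str,
                           value_name: str = "rpkm") -> None:
    df = pd.DataFrame({"gene": values.index, value_name: values.values})
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path: str) -> pd.DataFrame:
    """Library manifest TSV: library, species, library_size, file paths."""
    df = pd.read_csv(path, sep="\t")
    if "library_size" not in df.columns:
        raise ValueError("manifest needs a library_size column")
    if (df["library_size"] <= 0).any():
        raise ValueError("library_size must be positive")
    return df


def read_reads_fasta(path: str) -> list[tuple[str, str]]:
    """Read small-RNA reads from FASTA or FASTQ as (id, sequence) pairs."""
    fmt = "fastq" if path.endswith(("fastq", "fq")) else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, fmt)]
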