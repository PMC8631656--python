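"""Annotated-genome data model and readers/writers for FASTA, GFF3 and ortholog tables.

Every downstream stage of the pipeline operates on :class:`AnnotatedGenome`
objects: plain chromosome sequences plus an ordered list of gene features,
with orthology encoded as a shared ``ortholog_id`` label across strains.
Coordinates are 1-based inclusive throughout (the GFF3 convention); any
upstream-distance arithmetic converts explicitly at the computation site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeFormatError",
    "GenomeConsistencyError",
    "GeneFeature",
    "AnnotatedGenome",
    "OrthologMap",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "load_annotated_genome",
    "write_annotated_genome",
    "read_ortholog_table",
    "write_ortholog_table",
    "gene_start",
    "reverse_complement",
]

VALID_BASES = frozenset("ACGTN")


class GenomeFormatError(ValueError):
    """A file violates its format contract (FASTA/GFF3/TSV)."""


class GenomeConsistencyError(ValueError):
    """Sequence and annotation disagree (unknown chromosome, out-of-bounds gene)."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GeneFeature:
    """One gene: 1-based inclusive coordinates on a named chromosome."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    ortholog_id: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GenomeFormatError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in ("+", "-"):
            raise GenomeFormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chromosome, self.start, self.end)


def gene_start(feature: GeneFeature) -> int:
    """Translation-start-proximal coordinate on the coding strand.

    ``start`` for + genes, ``end`` for − genes; promoter offsets are measured
    upstream of this position.
    """
    return feature.start if feature.strand == "+" else feature.end


@dataclass
class AnnotatedGenome:
    """Chromosome sequences plus ordered gene features for one strain."""

    strain_id: str
    chromosomes: dict[str, str]
    genes: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=GeneFeature.sort_key)
        self.validate()

    def validate(self) -> None:
        seen_ids: set[str] = set()
        seen_locus: set[tuple[str, int, int, str]] = set()
        for g in self.genes:
            if g.gene_id in seen_ids:
                raise GenomeConsistencyError(
                    f"{self.strain_id}: duplicate gene id {g.gene_id}"
                )
            seen_ids.add(g.gene_id)
            locus = (g.chromosome, g.start, g.end, g.strand)
            if locus in seen_locus:
                raise GenomeConsistencyError(
                    f"{self.strain_id}: two genes at identical locus {locus}"
                )
            seen_locus.add(locus)
            if g.chromosome not in self.chromosomes:
                raise GenomeConsistencyError(
                    f"{self.strain_id}: gene {g.gene_id} on unknown chromosome "
                    f"{g.chromosome}"
                )
            if g.end > len(self.chromosomes[g.chromosome]):
                raise GenomeConsistencyError(
                    f"{self.strain_id}: gene {g.gene_id} exceeds chromosome "
                    f"{g.chromosome} length {len(self.chromosomes[g.chromosome])}"
                )

    # -- lookups -----------------------------------------------------------

    def gene_by_id(self, gene_id: str) -> GeneFeature:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"{self.strain_id}: no gene {gene_id}")

    def genes_on(self, chromosome: str) -> list[GeneFeature]:
        return [g for g in self.genes if g.chromosome == chromosome]

    def find_ortholog(self, ortholog_id: str) -> GeneFeature | None:
        hits = [g for g in self.genes if g.ortholog_id == ortholog_id]
        if len(hits) > 1:
            raise GenomeConsistencyError(
                f"{self.strain_id}: ortholog {ortholog_id} annotated "
                f"{len(hits)} times"
            )
        return hits[0] if hits else None

    def gene_sequence(self, feature: GeneFeature) -> str:
        """Coding-strand sequence of a gene (reverse-complemented for −)."""
        seq = self.chromosomes[feature.chromosome][feature.start - 1 : feature.end]
        return reverse_complement(seq) if feature.strand == "-" else seq

    def copy(self, strain_id: str | None = None) -> "AnnotatedGenome":
        return AnnotatedGenome(
            strain_id=strain_id or self.strain_id,
            chromosomes=dict(self.chromosomes),
            genes=list(self.genes),
        )

    def relabel_strain(self, strain_id: str) -> "AnnotatedGenome":
        genome = self.copy(strain_id=strain_id)
        genome.genes = [
            replace(g, gene_id=f"{strain_id}_{g.ortholog_id or g.gene_id}")
            for g in genome.genes
        ]
        return genome


@dataclass
class OrthologMap:
    """ortholog_id → {strain_id → gene_id} across all strains."""

    table: dict[str, dict[str, str]] = field(default_factory=dict)

    def add(self, ortholog_id: str, strain_id: str, gene_id: str) -> None:
        row = self.table.setdefault(ortholog_id, {})
        if strain_id in row:
            raise GenomeFormatError(
                f"ortholog {ortholog_id} assigned twice for strain {strain_id}"
            )
        row[strain_id] = gene_id

    def gene_for(self, ortholog_id: str, strain_id: str) -> str | None:
        return self.table.get(ortholog_id, {}).get(strain_id)

    def orthologs(self) -> list[str]:
        return list(self.table)

    def strains(self) -> list[str]:
        seen: dict[str, None] = {}
        for row in self.table.values():
            for s in row:
                seen.setdefault(s)
        return list(seen)

    def __len__(self) -> int:
        return len(self.table)


# -- FASTA -----------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into {name: uppercased sequence}.

    The record name is the first whitespace-delimited header token. Only
    A/C/G/T/N are accepted after case folding.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise GenomeFormatError(f"{path}: duplicate sequence name {rec.id}")
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise GenomeFormatError(
                f"{path}: record {rec.id} contains invalid characters {sorted(bad)}"
            )
        records[rec.id] = seq
    if not records:
        raise GenomeFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -- GFF3 ------------------------------------------------------------------


def read_gff(path: str | Path) -> list[GeneFeature]:
    """Read gene rows from a GFF3 file, sorted by (chromosome, start).

    Only rows of type ``gene`` are consumed; ``gene_id`` comes from the ID
    attribute and ``ortholog_id`` from an optional ``ortholog`` attribute.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[GeneFeature] = []
    for f in db.features_of_type("gene"):
        ids = f.attributes.get("ID")
        if not ids:
            raise GenomeFormatError(f"{path}: gene row without ID attribute")
        if f.end < f.start:
            raise GenomeFormatError(f"{path}: gene {ids[0]} has end < start")
        ortho = f.attributes.get("ortholog")
        features.append(
            GeneFeature(
                gene_id=ids[0],
                chromosome=f.seqid,
                start=f.start,
                end=f.end,
                strand=f.strand,
                ortholog_id=ortho[0] if ortho else None,
            )
        )
    return sorted(features, key=GeneFeature.sort_key)


def write_gff(genes: list[GeneFeature], path: str | Path, source: str = "transloscan") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=GeneFeature.sort_key):
            attrs = f"ID={g.gene_id}"
            if g.ortholog_id:
                attrs += f";ortholog={g.ortholog_id}"
            fh.write(
                "\t".join(
                    [
                        g.chromosome,
                        source,
                        "gene",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def load_annotated_genome(
    fasta: str | Path, gff: str | Path, strain_id: str
) -> AnnotatedGenome:
    """Read and cross-validate a FASTA + GFF3 pair into an AnnotatedGenome."""
    return AnnotatedGenome(
        strain_id=strain_id, chromosomes=read_fasta(fasta), genes=read_gff(gff)
    )


def write_annotated_genome(
    genome: AnnotatedGenome, fasta: str | Path, gff: str | Path
) -> None:
    write_fasta(genome.chromosomes, fasta)
    write_gff(genome.genes, gff)


# -- ortholog table --------------------------------------------------------


def read_ortholog_table(path: str | Path) -> OrthologMap:
    """Read a TSV with header ``ortholog_id`` then one column per strain.

    Empty cells mean the ortholog is absent in that strain.
    """
    omap = OrthologMap()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "ortholog_id":
            raise GenomeFormatError(f"{path}: first column must be 'ortholog_id'")
        strains = header[1:]
        seen_rows: set[str] = set()
        for line in fh:
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            ortholog_id = cells[0]
            if ortholog_id in seen_rows:
                raise GenomeFormatError(f"{path}: duplicate ortholog row {ortholog_id}")
            seen_rows.add(ortholog_id)
            for strain, cell in zip(strains, cells[1:]):
                if cell:
                    omap.add(ortholog_id, strain, cell)
    return omap


def write_ortholog_table(
    omap: OrthologMap, path: str | Path, strains: list[str] | None = None
) -> None:
    strains = strains if strains is not None else omap.strains()
    with open(path, "w") as fh:
        fh.write("\t".join(["ortholog_id", *strains]) + "\n")
        for ortholog_id in omap.orthologs():
            row = omap.table[ortholog_id]
            fh.write(
                "\t".join([ortholog_id, *[row.get(s, "") for s in strains]]) + "\n"
            )
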