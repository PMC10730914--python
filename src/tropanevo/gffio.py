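"""Genome annotation containers and standard-format I/O (GFF3, FASTA, Newick).

Internal coordinates are 0-based half-open; conversion to GFF3's 1-based
inclusive convention happens only at read/write time.  Only the
gene/mRNA/CDS feature subset is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._codon import translate


class ValidationError(ValueError):
    """Workspace/annotation consistency problem."""


@dataclass
class Gene:
    gene_id: str
    chrom: str
    start: int            # 0-based half-open span of the whole gene
    end: int
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)  # CDS chunks
    cds: str | None = None         # strand-resolved, includes terminal stop
    protein: str | None = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError(f"gene {self.gene_id}: empty span")


@dataclass
class GenomeAnnotation:
    """Ordered gene models per chromosome, with optional sequences."""

    species: str
    genes: dict[str, Gene] = field(default_factory=dict)
    chrom_seqs: dict[str, str] = field(default_factory=dict)
    _order: dict[str, list[str]] | None = None
    _rank: dict[str, tuple[str, int]] | None = None

    def add(self, gene: Gene) -> None:
        if gene.gene_id in self.genes:
            raise ValidationError(f"duplicate gene id {gene.gene_id}")
        self.genes[gene.gene_id] = gene
        self._order = self._rank = None

    def _index(self) -> None:
        order: dict[str, list[str]] = {}
        for g in self.genes.values():
            order.setdefault(g.chrom, []).append(g.gene_id)
        for chrom in order:
            order[chrom].sort(key=lambda gid: (self.genes[gid].start, gid))
        self._order = dict(sorted(order.items()))
        self._rank = {
            gid: (chrom, i)
            for chrom, gids in self._order.items()
            for i, gid in enumerate(gids)
        }

    @property
    def chromosomes(self) -> list[str]:
        if self._order is None:
            self._index()
        return list(self._order)

    def gene_order(self, chrom: str) -> list[str]:
        if self._order is None:
            self._index()
        return self._order.get(chrom, [])

    def rank_of(self, gene_id: str) -> tuple[str, int]:
        """(chromosome, 0-based position in gene order along it)."""
        if self._rank is None:
            self._index()
        return self._rank[gene_id]

    def proteome(self) -> dict[str, str]:
        return {
            gid: g.protein for gid, g in sorted(self.genes.items())
            if g.protein
        }

    def cds_store(self) -> dict[str, str]:
        return {gid: g.cds for gid, g in sorted(self.genes.items()) if g.cds}


# ---------------------------------------------------------------------------
# GFF3

def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for chrom in annotation.chromosomes:
        if chrom in annotation.chrom_seqs:
            lines.append(
                f"##sequence-region {chrom} 1 {len(annotation.chrom_seqs[chrom])}"
            )
        for gid in annotation.gene_order(chrom):
            g = annotation.genes[gid]
            lines.append(
                f"{chrom}\ttropanevo\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={gid}"
            )
            lines.append(
                f"{chrom}\ttropanevo\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={gid}.t1;Parent={gid}"
            )
            for k, (s, e) in enumerate(g.exons or [(g.start, g.end)]):
                lines.append(
                    f"{chrom}\ttropanevo\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t"
                    f"0\tID={gid}.cds{k};Parent={gid}.t1"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path, species: str) -> GenomeAnnotation:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique",
        keep_order=True, force=True,
    )
    ann = GenomeAnnotation(species=species)
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.attributes["ID"][0]
        exons = []
        for mrna in db.children(feat, featuretype="mRNA"):
            for cds in db.children(mrna, featuretype="CDS", order_by="start"):
                exons.append((cds.start - 1, cds.end))
        exons.sort()
        ann.add(
            Gene(
                gene_id=gid,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                exons=exons,
            )
        )
    return ann


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def attach_sequences(
    ann: GenomeAnnotation,
    proteins: dict[str, str] | None = None,
    cds: dict[str, str] | None = None,
    genomic: dict[str, str] | None = None,
    validate: bool = True,
) -> GenomeAnnotation:
    """Join FASTA sequences onto an annotation, cross-checking consistency."""
    errors = []
    if cds:
        for gid, seq in cds.items():
            if gid not in ann.genes:
                errors.append(f"CDS id {gid} not in GFF3")
                continue
            if len(seq) % 3:
                errors.append(f"gene {gid}: CDS length {len(seq)} not divisible by 3")
                continue
            ann.genes[gid].cds = seq
    if proteins:
        for gid, seq in proteins.items():
            if gid not in ann.genes:
                errors.append(f"protein id {gid} not in GFF3")
                continue
            ann.genes[gid].protein = seq
            g = ann.genes[gid]
            if validate and g.cds and translate(g.cds) != seq:
                errors.append(f"gene {gid}: protein is not the translated CDS")
    if genomic:
        ann.chrom_seqs.update(genomic)
    if errors:
        raise ValidationError("; ".join(errors))
    return ann
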