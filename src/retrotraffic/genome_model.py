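"""Data model and I/O for annotated genomes and the stage-labelled species tree.

Coordinates are 0-based half-open internally; GFF3 on disk is 1-based
inclusive.  The readers/writers in this module are the only place where the
conversion happens.  Exons of minus-strand genes are stored in transcription
order (reversed genomic order), so ``exons[0]`` is always the biological
first exon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import gffutils
from Bio import SeqIO

__all__ = [
    "GeneModel",
    "ChromosomeInfo",
    "AnnotationSet",
    "StagedTree",
    "PHYLO_STAGES",
    "longest_intron",
    "read_annotation",
    "write_annotation",
]

#: Phylogenetic stage labels, youngest (focal-species lineage) first.
PHYLO_STAGES: tuple[str, ...] = tuple(f"PS{i}" for i in range(1, 10))

OUTGROUP = "outgroup"


@dataclass
class GeneModel:
    """One gene: coordinates, exon structure and longest-isoform sequences.

    ``exons`` are 0-based half-open genomic intervals listed in
    transcription order; for minus-strand genes that is descending genomic
    order.  ``protein``/``cds`` come from the longest-protein isoform.
    """

    gene_id: str
    species_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    protein: str
    cds: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: at least one exon required")

    @property
    def exons_genomic(self) -> list[tuple[int, int]]:
        """Exons sorted by genomic start, regardless of strand."""
        return sorted(self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def exon_lengths(self) -> list[int]:
        """Exon lengths in transcription order (bp)."""
        return [e - s for s, e in self.exons]

    def intron_lengths(self) -> list[int]:
        ex = self.exons_genomic
        return [b[0] - a[1] for a, b in zip(ex, ex[1:])]

    def junction_residues(self) -> list[int]:
        """Protein residue index containing each exon–exon junction.

        A junction after ``p`` coding bases maps to residue ``p // 3``; a
        junction splitting a codon is assigned to the residue containing it.
        """
        out, p = [], 0
        for length in self.exon_lengths()[:-1]:
            p += length
            out.append(p // 3)
        return out

    def validate(self) -> None:
        ex = self.exons_genomic
        for (s, e) in ex:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside span")
        for a, b in zip(ex, ex[1:]):
            if b[0] < a[1]:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        span = self.end - self.start
        if not (3 * len(self.protein) <= len(self.cds) <= span):
            raise ValueError(
                f"{self.gene_id}: protein/CDS/span lengths inconsistent "
                f"({len(self.protein)} aa, {len(self.cds)} bp, {span} bp)"
            )


def longest_intron(gene: GeneModel) -> int:
    """Length in bp of the longest intron; 0 for single-exon genes."""
    lengths = gene.intron_lengths()
    return max(lengths) if lengths else 0


@dataclass
class ChromosomeInfo:
    """Chromosome identity used by the traffic direction classes.

    ``arm_group`` collapses chromosome arms (2R/2L -> "2", 3R/3L -> "3") so
    that same-arm-group movements count as intrachromosomal.
    """

    name: str
    sex_class: str  # "X_like" | "autosome"
    length: int
    gene_count: int = 0
    arm_group: str = ""

    def __post_init__(self) -> None:
        if self.sex_class not in ("X_like", "autosome"):
            raise ValueError(f"bad sex_class {self.sex_class!r}")
        if not self.arm_group:
            self.arm_group = self.name


@dataclass
class AnnotationSet:
    """All gene models of one species plus chromosome metadata and gene order."""

    species_id: str
    genes: dict[str, GeneModel]
    chromosomes: dict[str, ChromosomeInfo]
    gene_order: dict[str, list[str]] = field(default_factory=dict)
    unplaced: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.gene_order:
            self.rebuild_gene_order()

    def rebuild_gene_order(self) -> None:
        """Per-chromosome gene ids sorted by span start; refreshes gene counts."""
        order: dict[str, list[str]] = {c: [] for c in self.chromosomes}
        for g in self.genes.values():
            if g.chromosome in order:
                order[g.chromosome].append(g.gene_id)
            else:
                self.unplaced.add(g.gene_id)
        for chrom, ids in order.items():
            ids.sort(key=lambda gid: (self.genes[gid].start, gid))
            self.chromosomes[chrom].gene_count = len(ids)
        self.gene_order = order

    def position(self, gene_id: str) -> tuple[str, int]:
        """(chromosome, index in gene_order) of a placed gene."""
        chrom = self.genes[gene_id].chromosome
        return chrom, self.gene_order[chrom].index(gene_id)

    def neighbors(self, gene_id: str, window: int) -> list[tuple[int, str]]:
        """Flanking genes within ``window`` per side as (signed offset, gene_id)."""
        chrom, idx = self.position(gene_id)
        order = self.gene_order[chrom]
        out = []
        for off in range(-window, window + 1):
            if off == 0:
                continue
            j = idx + off
            if 0 <= j < len(order):
                out.append((off, order[j]))
        return out

    def validate(self) -> None:
        for g in self.genes.values():
            g.validate()
            if g.chromosome in self.chromosomes:
                if g.end > self.chromosomes[g.chromosome].length:
                    raise ValueError(f"{g.gene_id} beyond chromosome end")
        for chrom, ids in self.gene_order.items():
            starts = [self.genes[g].start for g in ids]
            if starts != sorted(starts):
                raise ValueError(f"gene_order on {chrom} not sorted by start")


# ---------------------------------------------------------------------------
# Species tree with stage-labelled focal root path
# ---------------------------------------------------------------------------


@dataclass
class StagedTree:
    """Rooted species tree whose focal-species root path is cut into stages.

    Each non-focal species carries the stage label of the focal-path segment
    immediately rootward of the node where its lineage attaches, i.e., the
    age a retrocopy must have to be shared with that species.  The focal
    species itself defines PS1 (the most recent stage); species flagged
    ``outgroup`` sit beyond PS9 and only confirm absence.
    """

    topology: dendropy.Tree
    focal_species: str
    stage_of_species: dict[str, str]
    stage_order: tuple[str, ...] = PHYLO_STAGES

    def __post_init__(self) -> None:
        labels = {t.taxon.label for t in self.topology.leaf_node_iter()}
        for sp, st in self.stage_of_species.items():
            if sp not in labels:
                raise ValueError(f"species {sp} not in tree")
            if st != OUTGROUP and st not in self.stage_order:
                raise ValueError(f"unknown stage {st!r} for {sp}")
        if self.focal_species not in labels:
            raise ValueError(f"focal species {self.focal_species} not in tree")

    def stage_index(self, stage: str) -> int:
        return self.stage_order.index(stage) + 1

    def is_outgroup(self, species: str) -> bool:
        return self.stage_of_species.get(species) == OUTGROUP

    def ingroup_species(self) -> list[str]:
        return [
            sp
            for sp, st in self.stage_of_species.items()
            if st != OUTGROUP and sp != self.focal_species
        ]

    @classmethod
    def from_files(cls, newick_path: str | Path, stage_tsv: str | Path) -> "StagedTree":
        """Read a Newick tree plus a species→stage table.

        The TSV has columns ``species`` and ``stage`` (PS2..PS9 or
        ``outgroup``); the focal species is the row labelled PS1.
        """
        tree = dendropy.Tree.get(path=str(newick_path), schema="newick")
        stage_of: dict[str, str] = {}
        focal = None
        with open(stage_tsv) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                if row["stage"] == "PS1":
                    focal = row["species"]
                else:
                    stage_of[row["species"]] = row["stage"]
        if focal is None:
            raise ValueError("stage table defines no PS1 focal species")
        return cls(topology=tree, focal_species=focal, stage_of_species=stage_of)

    def write(self, newick_path: str | Path, stage_tsv: str | Path) -> None:
        self.topology.write(path=str(newick_path), schema="newick")
        with open(stage_tsv, "w") as fh:
            fh.write("species\tstage\n")
            fh.write(f"{self.focal_species}\tPS1\n")
            for sp, st in sorted(self.stage_of_species.items()):
                fh.write(f"{sp}\t{st}\n")


# ---------------------------------------------------------------------------
# GFF3 / FASTA / TSV I/O
# ---------------------------------------------------------------------------


def _read_chromosome_table(path: str | Path) -> dict[str, ChromosomeInfo]:
    chroms: dict[str, ChromosomeInfo] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            chroms[row["name"]] = ChromosomeInfo(
                name=row["name"],
                sex_class=row["sex_class"],
                length=int(row["length"]),
                arm_group=row.get("arm_group", row["name"]),
            )
    return chroms


def _write_chromosome_table(chroms: Mapping[str, ChromosomeInfo], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tsex_class\tlength\tarm_group\n")
        for c in chroms.values():
            fh.write(f"{c.name}\t{c.sex_class}\t{c.length}\t{c.arm_group}\n")


def read_annotation(
    gff3_path: str | Path,
    protein_fasta: str | Path,
    cds_fasta: str | Path,
    chromosome_table: str | Path | None = None,
    species_id: str | None = None,
) -> AnnotationSet:
    """Build an :class:`AnnotationSet` from GFF3 + protein/CDS FASTA.

    One :class:`GeneModel` is kept per gene, from its longest-protein
    isoform (ties broken by lexicographic mRNA id).  FASTA records are keyed
    by mRNA id; an mRNA with no FASTA record is a hard error.  A gene whose
    CDS length disagrees with its protein length is warned about and
    excluded.  Genes on chromosomes absent from the chromosome table are
    flagged as unplaced: retained for alignment search but excluded from
    gene order and traffic statistics.
    """
    species_id = species_id or Path(gff3_path).stem
    prot = {r.id: str(r.seq) for r in SeqIO.parse(str(protein_fasta), "fasta")}
    cds = {r.id: str(r.seq) for r in SeqIO.parse(str(cds_fasta), "fasta")}

    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )

    genes: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        best = None  # (protein length, mRNA id, feature)
        for mrna in db.children(gene, featuretype="mRNA"):
            if mrna.id not in prot:
                raise KeyError(
                    f"mRNA {mrna.id} (gene {gene.id}) has no protein FASTA record"
                )
            key = (-len(prot[mrna.id]), mrna.id)
            if best is None or key < best[0]:
                best = (key, mrna)
        if best is None:
            continue
        mrna = best[1]
        if mrna.id not in cds:
            raise KeyError(f"mRNA {mrna.id} (gene {gene.id}) has no CDS FASTA record")
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        if not exons:
            exons = sorted(
                (f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")
            )
        if gene.strand == "-":
            exons = exons[::-1]
        p, c = prot[mrna.id], cds[mrna.id]
        if len(c) not in (3 * len(p), 3 * len(p) + 3):
            warnings.warn(
                f"{gene.id}: CDS length {len(c)} inconsistent with protein "
                f"length {len(p)}; gene excluded"
            )
            continue
        genes[gene.id] = GeneModel(
            gene_id=gene.id,
            species_id=species_id,
            chromosome=gene.seqid,
            strand=gene.strand,
            start=gene.start - 1,
            end=gene.end,
            exons=exons,
            protein=p,
            cds=c,
        )

    if chromosome_table is not None:
        chroms = _read_chromosome_table(chromosome_table)
    else:
        # Without metadata every seqid becomes an autosome-class chromosome.
        chroms = {}
        for g in genes.values():
            info = chroms.setdefault(
                g.chromosome,
                ChromosomeInfo(g.chromosome, "autosome", 0),
            )
            info.length = max(info.length, g.end)
    return AnnotationSet(species_id=species_id, genes=genes, chromosomes=chroms)


def write_annotation(ann: AnnotationSet, outdir: str | Path) -> dict[str, Path]:
    """Write GFF3 + protein/CDS FASTA + chromosome TSV; returns the paths.

    Inverse of :func:`read_annotation` for the formats this package itself
    produces (one mRNA per gene, CDS == exons).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff3": outdir / f"{ann.species_id}.gff3",
        "protein": outdir / f"{ann.species_id}.prot.fasta",
        "cds": outdir / f"{ann.species_id}.cds.fasta",
        "chromosomes": outdir / f"{ann.species_id}.chromosomes.tsv",
    }
    order = [g for chrom in sorted(ann.gene_order) for g in ann.gene_order[chrom]]
    order += sorted(ann.unplaced)
    with open(paths["gff3"], "w") as gff, open(paths["protein"], "w") as pf, open(
        paths["cds"], "w"
    ) as cf:
        gff.write("##gff-version 3\n")
        for gid in order:
            g = ann.genes[gid]
            mrna_id = f"{gid}.t1"
            base = f"{g.chromosome}\tretrotraffic"
            gff.write(
                f"{base}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={gid}\n"
            )
            gff.write(
                f"{base}\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={gid}\n"
            )
            for i, (s, e) in enumerate(g.exons_genomic, 1):
                gff.write(
                    f"{base}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
                gff.write(
                    f"{base}\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )
            pf.write(f">{mrna_id}\n{g.protein}\n")
            cf.write(f">{mrna_id}\n{g.cds}\n")
    _write_chromosome_table(ann.chromosomes, paths["chromosomes"])
    return paths
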