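"""Discovery of retrogene/parental gene pairs by protein alignment and
intron-loss evidence.

A retrocopy arises from reverse transcription of a spliced mRNA, so it lacks
its parent's introns.  The discovery filters are: local protein alignment
with identity > 30% and reciprocal alignment coverage > 70% of each protein,
at least one parental exon–exon junction bridged by >= 30 bp (10 aa) of
contiguous alignment on both sides without a retained intron at the mapped
position, and parent and retrocopy on different chromosomes (chromosome arms
2R/2L and 3R/3L count as one chromosome each).
"""

from __future__ import annotations

import itertools
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_model import AnnotationSet, ChromosomeInfo, GeneModel, longest_intron

__all__ = [
    "IdentificationConfig",
    "PairEvidence",
    "RetroPair",
    "align_protein_pair",
    "candidate_pairs",
    "junction_support",
    "assign_parent_retro",
    "classify_direction",
    "discover_pairs",
    "write_pairs_tsv",
]

X_TO_A = "X->A"
A_TO_A = "A->A"
A_TO_X = "A->X"
DIRECTIONS = (X_TO_A, A_TO_A, A_TO_X)


@dataclass
class IdentificationConfig:
    """Thresholds of the discovery filters.

    junction_flank_bp is the contiguous alignment required on each side of a
    parental exon junction (30 bp = 10 aa); short_intron_bp marks parents
    whose introns are all shorter than this as ambiguous, triggering the
    synteny tiebreak for parent/retro assignment.
    """

    min_identity: float = 0.30
    min_reciprocal_coverage: float = 0.70
    junction_flank_bp: int = 30
    short_intron_bp: int = 50
    require_interchromosomal: bool = True
    # alignment engine parameters (affine-gap Smith-Waterman)
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    # seeding prefilter: only align pairs sharing >= seed_min_kmers k-mers
    seed_kmer: int = 5
    seed_min_kmers: int = 2
    use_seed_prefilter: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if not (0 < self.min_reciprocal_coverage <= 1):
            raise ValueError("min_reciprocal_coverage must be in (0, 1]")
        if self.junction_flank_bp % 3:
            raise ValueError("junction_flank_bp must be a multiple of 3")

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        # first gapped column costs open+extend (BLAST convention)
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass
class PairEvidence:
    """Alignment evidence for one candidate paralogous pair."""

    gene_a: str
    gene_b: str
    identity: float
    coverage_a: float
    coverage_b: float
    junctions_supported: int = 0
    aligned_region: tuple[tuple[int, int], tuple[int, int]] | None = None
    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...] = ()
    score: float = 0.0

    def swapped(self) -> "PairEvidence":
        """Same evidence with gene_a/gene_b roles exchanged."""
        return PairEvidence(
            gene_a=self.gene_b,
            gene_b=self.gene_a,
            identity=self.identity,
            coverage_a=self.coverage_b,
            coverage_b=self.coverage_a,
            junctions_supported=self.junctions_supported,
            aligned_region=(
                None
                if self.aligned_region is None
                else (self.aligned_region[1], self.aligned_region[0])
            ),
            blocks=tuple((b, a) for a, b in self.blocks),
            score=self.score,
        )


@dataclass
class RetroPair:
    """A parental gene / retrogene pair with direction and (later) stage."""

    parent_id: str
    retro_id: str
    direction: str
    parent_chromosome: str
    retro_chromosome: str
    evidence: PairEvidence
    stage: str | None = None


def align_protein_pair(
    a: str, b: str, cfg: IdentificationConfig | None = None,
    aligner: Align.PairwiseAligner | None = None,
    gene_a: str = "a", gene_b: str = "b",
) -> PairEvidence:
    """Local (Smith–Waterman) alignment of two proteins.

    Identity is identities / alignment columns (gap columns included);
    coverage of each gene is its aligned span / full protein length.
    """
    if not a or not b:
        raise ValueError("cannot align an empty protein sequence")
    cfg = cfg or IdentificationConfig()
    aligner = aligner or cfg.make_aligner()
    alignments = aligner.align(a, b)
    try:
        aln = alignments[0]
    except IndexError:  # no positive-scoring local alignment
        return PairEvidence(gene_a, gene_b, 0.0, 0.0, 0.0)
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    blocks_a, blocks_b = aln.aligned
    a_start, a_end = int(blocks_a[0][0]), int(blocks_a[-1][1])
    b_start, b_end = int(blocks_b[0][0]), int(blocks_b[-1][1])
    return PairEvidence(
        gene_a=gene_a,
        gene_b=gene_b,
        identity=counts.identities / columns if columns else 0.0,
        coverage_a=(a_end - a_start) / len(a),
        coverage_b=(b_end - b_start) / len(b),
        aligned_region=((a_start, a_end), (b_start, b_end)),
        blocks=tuple(
            ((int(pa[0]), int(pa[1])), (int(pb[0]), int(pb[1])))
            for pa, pb in zip(blocks_a, blocks_b)
        ),
        score=float(aln.score),
    )


def _seed_pairs(proteins: Mapping[str, str], k: int, min_shared: int) -> set[tuple[str, str]]:
    """Unordered id pairs sharing at least ``min_shared`` distinct k-mers."""
    index: dict[str, set[str]] = defaultdict(set)
    for gid, seq in proteins.items():
        for i in range(len(seq) - k + 1):
            index[seq[i : i + k]].add(gid)
    shared: dict[tuple[str, str], int] = defaultdict(int)
    for members in index.values():
        if len(members) < 2:
            continue
        for pair in itertools.combinations(sorted(members), 2):
            shared[pair] += 1
    return {pair for pair, n in shared.items() if n >= min_shared}


def candidate_pairs(
    ann: AnnotationSet, cfg: IdentificationConfig | None = None
) -> list[PairEvidence]:
    """All unordered gene pairs passing the identity and coverage filters.

    With the default seeding prefilter only pairs sharing at least two
    5-mers are aligned; sequences below the 30% identity threshold
    essentially never share seeds, so the filter result is unchanged at a
    fraction of the alignment cost.
    """
    cfg = cfg or IdentificationConfig()
    if not ann.genes:
        raise ValueError("empty annotation set")
    proteins = {gid: g.protein for gid, g in ann.genes.items() if g.protein}
    if cfg.use_seed_prefilter:
        pairs = sorted(_seed_pairs(proteins, cfg.seed_kmer, cfg.seed_min_kmers))
    else:
        pairs = list(itertools.combinations(sorted(proteins), 2))
    aligner = cfg.make_aligner()
    out: list[PairEvidence] = []
    for ga, gb in pairs:
        ev = align_protein_pair(
            proteins[ga], proteins[gb], cfg, aligner=aligner, gene_a=ga, gene_b=gb
        )
        if (
            ev.identity > cfg.min_identity
            and ev.coverage_a > cfg.min_reciprocal_coverage
            and ev.coverage_b > cfg.min_reciprocal_coverage
        ):
            out.append(ev)
    out.sort(key=lambda e: (e.gene_a, e.gene_b))
    return out


def junction_support(
    parent: GeneModel,
    retro: GeneModel,
    ev: PairEvidence,
    cfg: IdentificationConfig | None = None,
) -> int:
    """Number of parental exon junctions supported by the alignment.

    A junction is supported when it lies inside a single gapless aligned
    block with >= junction_flank_bp/3 residues aligned on both sides, and
    the retrogene has no exon junction (retained intron) at the mapped
    position.  ``ev`` must have ``gene_a == parent``.
    """
    cfg = cfg or IdentificationConfig()
    if parent.n_exons < 2:
        raise ValueError(
            f"{parent.gene_id} is single-exon and cannot show intron loss"
        )
    if ev.gene_a != parent.gene_id:
        ev = ev.swapped()
    flank = cfg.junction_flank_bp // 3
    retro_junctions = set(retro.junction_residues())
    supported = 0
    for j in parent.junction_residues():
        for (pa_s, pa_e), (pb_s, pb_e) in ev.blocks:
            if pa_s <= j - flank and j + flank <= pa_e:
                mapped = pb_s + (j - pa_s)
                if mapped not in retro_junctions:
                    supported += 1
                break
    return supported


def assign_parent_retro(
    a: GeneModel,
    b: GeneModel,
    synteny_scores: Mapping[str, int] | None = None,
) -> tuple[GeneModel, GeneModel]:
    """Decide which gene of a pair is parental.

    The gene with more introns is the parent.  When the putative parent's
    introns are all short (< 50 bp, a mis-assignment risk) or exon counts
    tie, the gene with strictly more conserved synteny across species wins;
    an unresolved pair raises ValueError (callers drop it with the reason).
    """
    def by_synteny() -> tuple[GeneModel, GeneModel] | None:
        if synteny_scores is None:
            return None
        sa = synteny_scores.get(a.gene_id, 0)
        sb = synteny_scores.get(b.gene_id, 0)
        if sa > sb:
            return a, b
        if sb > sa:
            return b, a
        return None

    if a.n_exons == b.n_exons:
        resolved = by_synteny()
        if resolved is None:
            raise ValueError(
                f"{a.gene_id}/{b.gene_id}: equal exon counts and no synteny "
                "tiebreak; pair dropped"
            )
        return resolved

    parent, retro = (a, b) if a.n_exons > b.n_exons else (b, a)
    if longest_intron(parent) < IdentificationConfig().short_intron_bp:
        resolved = by_synteny()
        if resolved is not None:
            return resolved
        if synteny_scores is not None:
            raise ValueError(
                f"{a.gene_id}/{b.gene_id}: short-intron parent and synteny "
                "tie; pair dropped"
            )
        # no synteny information available: keep the intron-count call
    return parent, retro


def classify_direction(
    parent_chrom: str,
    retro_chrom: str,
    chromosomes: Mapping[str, ChromosomeInfo],
    require_interchromosomal: bool = True,
) -> str | None:
    """Direction class of a movement, or None for intrachromosomal pairs.

    Arms collapse via ``arm_group``: a 2R -> 2L movement is within
    chromosome 2 and is excluded when interchromosomal pairs are required.
    """
    try:
        src = chromosomes[parent_chrom]
        dst = chromosomes[retro_chrom]
    except KeyError as exc:
        raise KeyError(f"unclassified chromosome {exc.args[0]!r}") from exc
    if src.arm_group == dst.arm_group:
        return None if require_interchromosomal else A_TO_A
    if src.sex_class == "X_like":
        return X_TO_A
    if dst.sex_class == "X_like":
        return A_TO_X
    return A_TO_A


def discover_pairs(
    ann: AnnotationSet,
    cfg: IdentificationConfig | None = None,
    synteny_score_fn: Callable[[str], int] | None = None,
) -> list[RetroPair]:
    """Full within-species discovery: screen, junction filter, parent
    assignment, direction classification, one-parent-per-retrogene policy.

    ``synteny_score_fn`` maps a gene id to its cross-species synteny
    conservation score; it is consulted only for ambiguous pairs (equal exon
    counts or short-intron parents).
    """
    cfg = cfg or IdentificationConfig()
    scores_cache: dict[str, int] = {}

    def scores_for(*gids: str) -> Mapping[str, int] | None:
        if synteny_score_fn is None:
            return None
        for gid in gids:
            if gid not in scores_cache:
                scores_cache[gid] = synteny_score_fn(gid)
        return scores_cache

    pairs: list[RetroPair] = []
    for ev in candidate_pairs(ann, cfg):
        a, b = ann.genes[ev.gene_a], ann.genes[ev.gene_b]
        ambiguous = (
            a.n_exons == b.n_exons
            or longest_intron(a if a.n_exons > b.n_exons else b)
            < cfg.short_intron_bp
        )
        try:
            parent, retro = assign_parent_retro(
                a, b, scores_for(a.gene_id, b.gene_id) if ambiguous else None
            )
        except ValueError as exc:
            warnings.warn(str(exc))
            continue
        if parent.n_exons < 2 or retro.n_exons >= parent.n_exons:
            continue
        direction = classify_direction(
            parent.chromosome,
            retro.chromosome,
            ann.chromosomes,
            cfg.require_interchromosomal,
        )
        if direction is None:
            continue
        if parent.chromosome in ann.unplaced or retro.chromosome in ann.unplaced:
            continue
        n_junc = junction_support(parent, retro, ev, cfg)
        if n_junc < 1:
            continue
        ev_oriented = ev if ev.gene_a == parent.gene_id else ev.swapped()
        ev_oriented.junctions_supported = n_junc
        pairs.append(
            RetroPair(
                parent_id=parent.gene_id,
                retro_id=retro.gene_id,
                direction=direction,
                parent_chromosome=parent.chromosome,
                retro_chromosome=retro.chromosome,
                evidence=ev_oriented,
            )
        )

    # one-parent policy: keep the highest-identity parent per retrogene,
    # ties broken by longest parent protein then id
    best: dict[str, RetroPair] = {}
    for p in pairs:
        key = (
            p.evidence.identity,
            len(ann.genes[p.parent_id].protein),
            p.parent_id,
        )
        cur = best.get(p.retro_id)
        if cur is None or key > (
            cur.evidence.identity,
            len(ann.genes[cur.parent_id].protein),
            cur.parent_id,
        ):
            best[p.retro_id] = p
    return sorted(best.values(), key=lambda p: (p.parent_id, p.retro_id))


def write_pairs_tsv(pairs: Iterable[RetroPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "parent_id\tretro_id\tidentity\tcoverage_parent\tcoverage_retro\t"
            "junctions_supported\tdirection\tstage\n"
        )
        for p in pairs:
            e = p.evidence
            fh.write(
                f"{p.parent_id}\t{p.retro_id}\t{e.identity:.4f}\t"
                f"{e.coverage_a:.4f}\t{e.coverage_b:.4f}\t"
                f"{e.junctions_supported}\t{p.direction}\t{p.stage or 'NA'}\n"
            )
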