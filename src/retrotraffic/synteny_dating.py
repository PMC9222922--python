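"""Synteny-based dating of retroduplication events onto phylogenetic stages.

A retrocopy's age is the most distant stage (PS1 youngest .. PS9 oldest)
whose species show the retrogene present with conserved local gene order:
at least two flanking genes whose orthologs keep their relative position
around the retrogene's ortholog.  Presence without synteny support does not
advance the call; outgroup species only confirm absence beyond the called
stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .genome_model import AnnotationSet, StagedTree
from .retrocopy_id import RetroPair, DIRECTIONS, X_TO_A, A_TO_A, A_TO_X

__all__ = [
    "OrthologMap",
    "SyntenyConfig",
    "StageCall",
    "synteny_conserved",
    "synteny_score",
    "date_pair",
    "group_stages",
    "write_stage_calls",
]


class OrthologMap:
    """Cross-species gene-id correspondences.

    Stored as (species_a, gene_a) -> {species_b: gene_b}; symmetric.
    """

    def __init__(self) -> None:
        self._map: dict[tuple[str, str], dict[str, str]] = {}

    def add(self, species_a: str, gene_a: str, species_b: str, gene_b: str) -> None:
        self._map.setdefault((species_a, gene_a), {})[species_b] = gene_b
        self._map.setdefault((species_b, gene_b), {})[species_a] = gene_a

    def get(self, species: str, gene: str, other_species: str) -> str | None:
        return self._map.get((species, gene), {}).get(other_species)

    def covers_species(self, species: str) -> bool:
        return any(sp == species or species in m for (sp, _), m in self._map.items())

    @classmethod
    def from_shared_basenames(
        cls, annotations: Mapping[str, AnnotationSet], sep: str = "_"
    ) -> "OrthologMap":
        """Orthology by shared gene basename (id = f"{species}{sep}{base}").

        This is the convention of the synthetic-data generator; real data
        should use :meth:`from_tsv` with an externally computed table.
        """
        by_base: dict[str, list[tuple[str, str]]] = {}
        for sp, ann in annotations.items():
            for gid in ann.genes:
                base = gid.split(sep, 1)[1] if gid.startswith(sp + sep) else gid
                by_base.setdefault(base, []).append((sp, gid))
        om = cls()
        for members in by_base.values():
            for i, (sa, ga) in enumerate(members):
                for sb, gb in members[i + 1 :]:
                    if sa != sb:
                        om.add(sa, ga, sb, gb)
        return om

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologMap":
        om = cls()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                om.add(row["species_a"], row["gene_a"], row["species_b"], row["gene_b"])
        return om

    def write_tsv(self, path: str | Path) -> None:
        seen = set()
        with open(path, "w") as fh:
            fh.write("species_a\tgene_a\tspecies_b\tgene_b\n")
            for (sa, ga), others in sorted(self._map.items()):
                for sb, gb in sorted(others.items()):
                    if ((sb, gb), (sa, ga)) in seen:
                        continue
                    seen.add(((sa, ga), (sb, gb)))
                    fh.write(f"{sa}\t{ga}\t{sb}\t{gb}\n")


@dataclass
class SyntenyConfig:
    """Neighborhood rule: >= min_conserved_neighbors of the flank_window
    genes per side must keep their relative order around the ortholog."""

    ortholog_map: OrthologMap
    min_conserved_neighbors: int = 2
    flank_window: int = 10

    def __post_init__(self) -> None:
        if self.min_conserved_neighbors < 1:
            raise ValueError("min_conserved_neighbors must be >= 1")
        if self.flank_window < self.min_conserved_neighbors:
            raise ValueError("flank_window must be >= min_conserved_neighbors")


@dataclass
class StageCall:
    pair_id: str
    stage: str
    supporting_species: list[str]
    outgroup_checked: bool = False


def synteny_conserved(
    focal_gene: str,
    focal_ann: AnnotationSet,
    other_ann: AnnotationSet,
    cfg: SyntenyConfig,
) -> bool:
    """True iff the gene's ortholog in ``other_ann`` keeps conserved local
    gene order.

    A flanking gene at signed offset d from the focal gene counts as
    conserved when its ortholog sits at the same signed offset from the
    focal gene's ortholog in the other species (same chromosome).  At least
    ``min_conserved_neighbors`` such genes are required.
    """
    if not cfg.ortholog_map.covers_species(other_ann.species_id):
        raise KeyError(f"species {other_ann.species_id} missing from ortholog map")
    om = cfg.ortholog_map
    ortho = om.get(focal_ann.species_id, focal_gene, other_ann.species_id)
    if ortho is None or ortho not in other_ann.genes:
        return False
    if other_ann.genes[ortho].chromosome not in other_ann.gene_order:
        return False
    o_chrom, o_idx = other_ann.position(ortho)
    o_order = other_ann.gene_order[o_chrom]
    conserved = 0
    for offset, flank_gid in focal_ann.neighbors(focal_gene, cfg.flank_window):
        flank_ortho = om.get(focal_ann.species_id, flank_gid, other_ann.species_id)
        if flank_ortho is None or flank_ortho not in other_ann.genes:
            continue
        j = o_idx + offset
        if 0 <= j < len(o_order) and o_order[j] == flank_ortho:
            conserved += 1
            if conserved >= cfg.min_conserved_neighbors:
                return True
    return False


def synteny_score(
    gene: str,
    focal_ann: AnnotationSet,
    others: Iterable[AnnotationSet],
    cfg: SyntenyConfig,
) -> int:
    """Number of other species in which the gene's local order is conserved.

    Used as the tiebreak for parent/retrogene assignment: the parental gene
    of a pair has deeper gene-order conservation than the inserted copy.
    """
    return sum(
        synteny_conserved(gene, focal_ann, other, cfg) for other in others
    )


def date_pair(
    pair: RetroPair,
    annotations: Mapping[str, AnnotationSet],
    tree: StagedTree,
    cfg: SyntenyConfig,
) -> StageCall:
    """Stage of the most distant species with retrogene presence + synteny.

    PS1 when only the focal species carries the retrogene.  Outgroup
    species are inspected only to set ``outgroup_checked`` (absence beyond
    the called stage confirmed).
    """
    focal_ann = annotations[tree.focal_species]
    if pair.retro_id not in focal_ann.genes:
        raise KeyError(f"retrogene {pair.retro_id} absent from focal annotation")
    supporting = [tree.focal_species]
    best = 1  # PS1
    for sp in tree.ingroup_species():
        if sp not in annotations:
            continue
        if synteny_conserved(pair.retro_id, focal_ann, annotations[sp], cfg):
            supporting.append(sp)
            best = max(best, tree.stage_index(tree.stage_of_species[sp]))
    outgroup_checked = False
    for sp, st in tree.stage_of_species.items():
        if tree.is_outgroup(sp) and sp in annotations:
            ortho = cfg.ortholog_map.get(tree.focal_species, pair.retro_id, sp)
            present = ortho is not None and ortho in annotations[sp].genes
            outgroup_checked = not (
                present and synteny_conserved(pair.retro_id, focal_ann, annotations[sp], cfg)
            )
    return StageCall(
        pair_id=f"{pair.parent_id}:{pair.retro_id}",
        stage=tree.stage_order[best - 1],
        supporting_species=supporting,
        outgroup_checked=outgroup_checked,
    )


# stage groupings used by the traffic analysis
YOUNG_STAGES = tuple(f"PS{i}" for i in range(1, 8))   # heteromorphic-X lineages
OLD_STAGES = ("PS8", "PS9")                            # homomorphic lineages
YOUNGEST_STAGES = tuple(f"PS{i}" for i in range(1, 5))


def group_stages(pairs: Iterable[RetroPair]) -> dict[str, "MovementCounts"]:
    """Direction counts per age group (young PS1-7, old PS8-9, and the finer
    PS1-4 / PS5-7 split of the young group)."""
    from .traffic_stats import MovementCounts  # avoid import cycle

    groups = {
        "young": MovementCounts(),
        "old": MovementCounts(),
        "young_ps1_4": MovementCounts(),
        "young_ps5_7": MovementCounts(),
    }
    for p in pairs:
        if p.stage is None:
            raise ValueError(f"pair {p.parent_id}:{p.retro_id} is not staged")
        targets = []
        if p.stage in YOUNG_STAGES:
            targets.append("young")
            targets.append("young_ps1_4" if p.stage in YOUNGEST_STAGES else "young_ps5_7")
        elif p.stage in OLD_STAGES:
            targets.append("old")
        else:
            raise ValueError(f"unknown stage {p.stage!r}")
        for t in targets:
            groups[t].add(p.direction)
    return groups


def write_stage_calls(calls: Iterable[StageCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pair_id\tstage\tsupporting_species\toutgroup_checked\n")
        for c in calls:
            fh.write(
                f"{c.pair_id}\t{c.stage}\t{','.join(c.supporting_species)}\t"
                f"{int(c.outgroup_checked)}\n"
            )
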