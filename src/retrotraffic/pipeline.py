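"""End-to-end convenience driver: discovery -> dating -> traffic counts."""

from __future__ import annotations

from typing import Mapping

from .genome_model import AnnotationSet, StagedTree
from .retrocopy_id import IdentificationConfig, RetroPair, discover_pairs
from .synteny_dating import (
    OrthologMap,
    SyntenyConfig,
    date_pair,
    group_stages,
    synteny_score,
)

__all__ = ["analyze_clade"]


def analyze_clade(
    annotations: Mapping[str, AnnotationSet],
    tree: StagedTree,
    id_cfg: IdentificationConfig | None = None,
    syn_cfg: SyntenyConfig | None = None,
) -> list[RetroPair]:
    """Discover retrogene/parental pairs in the focal species and date each
    onto its phylogenetic stage.

    When no synteny configuration is given, orthology falls back to shared
    gene basenames (the synthetic-data convention).
    """
    id_cfg = id_cfg or IdentificationConfig()
    if syn_cfg is None:
        syn_cfg = SyntenyConfig(OrthologMap.from_shared_basenames(dict(annotations)))
    focal_ann = annotations[tree.focal_species]
    others = [
        annotations[sp]
        for sp in tree.ingroup_species()
        if sp in annotations
    ]

    def score(gene_id: str) -> int:
        return synteny_score(gene_id, focal_ann, others, syn_cfg)

    pairs = discover_pairs(focal_ann, id_cfg, synteny_score_fn=score)
    for p in pairs:
        p.stage = date_pair(p, annotations, tree, syn_cfg).stage
    return pairs
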