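"""Protein alignment evidence, intron-loss junction support, parent
assignment and direction classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from Bio.Align import substitution_matrices

from retrotraffic.genome_model import ChromosomeInfo, GeneModel
from retrotraffic.retrocopy_id import (
    IdentificationConfig,
    align_protein_pair,
    assign_parent_retro,
    candidate_pairs,
    classify_direction,
    discover_pairs,
    junction_support,
)
from retrotraffic.synthetic_data import AMINO_ACIDS, PlantedEvent, SimScenario, simulate_clade


def gene_from_exon_bp(protein, exon_bp, gene_id="g", chrom="2", intron=100):
    """GeneModel with given protein and exon bp lengths (transcription order)."""
    assert sum(exon_bp) == 3 * len(protein) + 3
    exons, pos = [], 0
    for i, ln in enumerate(exon_bp):
        exons.append((pos, pos + ln))
        pos += ln + (intron if i < len(exon_bp) - 1 else 0)
    return GeneModel(
        gene_id=gene_id, species_id="sp", chromosome=chrom, strand="+",
        start=0, end=exons[-1][1], exons=exons,
        protein=protein, cds="N" * (3 * len(protein) + 3),
    )


def random_protein(rng, n):
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


# ---------------------------------------------------------------------------
# alignment evidence
# ---------------------------------------------------------------------------


def test_self_alignment_is_perfect():
    seq = random_protein(np.random.default_rng(0), 100)
    ev = align_protein_pair(seq, seq)
    assert ev.identity == 1.0
    assert ev.coverage_a == ev.coverage_b == 1.0


def test_truncation_halves_coverage():
    b = random_protein(np.random.default_rng(1), 200)
    a = b[:100]
    ev = align_protein_pair(a, b)
    assert ev.coverage_a >= 0.95
    assert abs(ev.coverage_b - 0.5) <= 0.05


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        align_protein_pair("", "MKL")


def test_unrelated_proteins_fail_filters():
    """Random 100-aa pairs never satisfy identity > 0.30 AND reciprocal
    coverage > 0.70 simultaneously."""
    rng = np.random.default_rng(2)
    cfg = IdentificationConfig()
    for _ in range(50):
        ev = align_protein_pair(random_protein(rng, 100), random_protein(rng, 100))
        passed = (
            ev.identity > cfg.min_identity
            and ev.coverage_a > cfg.min_reciprocal_coverage
            and ev.coverage_b > cfg.min_reciprocal_coverage
        )
        assert not passed


def _gotoh_local_score(a, b, matrix, open_cost=12, extend_cost=1):
    """Exhaustive affine-gap Smith-Waterman DP, independent of the engine."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - open_cost, E[i, j - 1] - extend_cost)
            F[i, j] = max(H[i - 1, j] - open_cost, F[i - 1, j] - extend_cost)
            s = matrix[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    a=st.text(alphabet="ACDE", min_size=1, max_size=20),
    b=st.text(alphabet="ACDE", min_size=1, max_size=20),
)
def test_alignment_score_matches_dp_oracle(a, b):
    matrix = substitution_matrices.load("BLOSUM62")
    ev = align_protein_pair(a, b)
    assert ev.score == pytest.approx(_gotoh_local_score(a, b, matrix))


# ---------------------------------------------------------------------------
# candidate screening on planted worlds
# ---------------------------------------------------------------------------


def test_single_planted_retrocopy_recovered_among_background():
    sc = SimScenario(
        seed=3,
        n_background_genes=50,
        planted_events=[PlantedEvent("X->A", "PS3", identity=0.95)],
        plant_decoys=False,
    )
    annotations, _, ledger = simulate_clade(sc)
    pairs = candidate_pairs(annotations["focal"])
    assert len(pairs) == 1
    ev = ledger.real_events()[0]
    assert {pairs[0].gene_a, pairs[0].gene_b} == {ev.parent_id, ev.retro_id}


def test_low_identity_homolog_rejected():
    rng = np.random.default_rng(4)
    base = random_protein(rng, 150)
    from retrotraffic.synthetic_data import _mutate_to_identity

    decoy = _mutate_to_identity(rng, base, 0.25)
    ev = align_protein_pair(base, decoy)
    assert ev.identity <= 0.30 or min(ev.coverage_a, ev.coverage_b) <= 0.70


def test_truncated_pseudocopy_fails_coverage():
    rng = np.random.default_rng(5)
    base = random_protein(rng, 200)
    ev = align_protein_pair(base, base[: int(0.6 * len(base))])
    assert ev.coverage_a <= 0.70  # reciprocal coverage filter fails


# ---------------------------------------------------------------------------
# junction support
# ---------------------------------------------------------------------------


def make_pair(parent_exon_bp, retro_exon_bp, n_aa=60):
    protein = random_protein(np.random.default_rng(6), n_aa)
    parent = gene_from_exon_bp(protein, parent_exon_bp, "parent", chrom="X")
    retro = gene_from_exon_bp(protein, retro_exon_bp, "retro", chrom="2")
    ev = align_protein_pair(parent.protein, retro.protein,
                            gene_a="parent", gene_b="retro")
    return parent, retro, ev


def test_three_exon_parent_single_exon_retro_two_junctions():
    """The canonical structure: 3 exons in the parent, one in the retrogene,
    full-length alignment -> both junctions supported."""
    parent, retro, ev = make_pair([60, 60, 63], [183])
    assert junction_support(parent, retro, ev) == 2


def test_junction_too_close_to_alignment_end_unsupported():
    parent, retro, ev = make_pair([15, 168], [183])  # junction at residue 5
    assert junction_support(parent, retro, ev) == 0


def test_retained_intron_blocks_that_junction_only():
    # retro keeps an intron exactly at the parent's first junction
    parent, retro, ev = make_pair([60, 60, 63], [60, 123])
    assert junction_support(parent, retro, ev) == 1


def test_single_exon_parent_is_an_error():
    parent, retro, ev = make_pair([183], [183])
    with pytest.raises(ValueError):
        junction_support(parent, retro, ev)


# ---------------------------------------------------------------------------
# parent assignment and direction
# ---------------------------------------------------------------------------


def test_more_introns_wins_parenthood():
    protein = random_protein(np.random.default_rng(7), 60)
    a = gene_from_exon_bp(protein, [60, 60, 63], "multi")
    b = gene_from_exon_bp(protein, [183], "single", chrom="3")
    parent, retro = assign_parent_retro(a, b)
    assert parent.gene_id == "multi"


def test_short_intron_parent_confirmed_by_synteny():
    protein = random_protein(np.random.default_rng(8), 60)
    a = gene_from_exon_bp(protein, [60, 60, 63], "shortintron", intron=40)
    b = gene_from_exon_bp(protein, [90, 93], "other", chrom="3")
    parent, retro = assign_parent_retro(a, b, {"shortintron": 8, "other": 2})
    assert parent.gene_id == "shortintron"


def test_equal_exons_and_synteny_tie_dropped():
    protein = random_protein(np.random.default_rng(9), 60)
    a = gene_from_exon_bp(protein, [90, 93], "a")
    b = gene_from_exon_bp(protein, [90, 93], "b", chrom="3")
    with pytest.raises(ValueError, match="dropped"):
        assign_parent_retro(a, b, {"a": 3, "b": 3})


CHROMS = {
    "X": ChromosomeInfo("X", "X_like", 100, arm_group="X"),
    "2R": ChromosomeInfo("2R", "autosome", 100, arm_group="2"),
    "2L": ChromosomeInfo("2L", "autosome", 100, arm_group="2"),
    "3L": ChromosomeInfo("3L", "autosome", 100, arm_group="3"),
}


@pytest.mark.parametrize(
    "parent_chrom,retro_chrom,expected",
    [
        ("X", "2L", "X->A"),
        ("2R", "2L", None),  # same arm group -> intrachromosomal, excluded
        ("3L", "X", "A->X"),
        ("2R", "3L", "A->A"),
    ],
)
def test_classify_direction(parent_chrom, retro_chrom, expected):
    assert classify_direction(parent_chrom, retro_chrom, CHROMS) == expected


def test_unclassified_chromosome_is_error():
    with pytest.raises(KeyError):
        classify_direction("X", "UNKN_scaffold", CHROMS)


# ---------------------------------------------------------------------------
# whole-discovery properties
# ---------------------------------------------------------------------------


def test_discovery_invariant_to_gene_ordering(world):
    from retrotraffic.genome_model import AnnotationSet

    annotations, _, _ = world
    ann = annotations["focal"]
    reversed_ann = AnnotationSet(
        species_id=ann.species_id,
        genes=dict(reversed(list(ann.genes.items()))),
        chromosomes=ann.chromosomes,
    )
    key = lambda pairs: [(p.parent_id, p.retro_id, p.direction) for p in pairs]
    assert key(discover_pairs(ann)) == key(discover_pairs(reversed_ann))


def test_decoys_never_reported(world, staged_pairs):
    _, _, ledger = world
    found = {p.retro_id for p in staged_pairs}
    decoys = {e.retro_id for e in ledger.decoy_events()}
    assert not (found & decoys)
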