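"""Synthetic test worlds: annotated multi-species clades with planted
retroduplication events and expression matrices with known effects.

The generator emulates the structure of the real inputs — per-species gene
models on one X-like chromosome and two autosomes, a ladder species tree
whose focal root path is cut into nine phylogenetic stages, testis/ovary
expression with configurable sex-bias effect sizes, and spermatogenesis
stage series carrying the MSCI motif (X-linked parents declining after the
premeiotic stage, autosomal retrocopies rising).  Every planted event and
expression effect is recorded in a ground-truth ledger so pipeline output
can be joined against the truth.

It deliberately does not model molecular evolution (no codon models, indels
or selection): background genes are identical across species and planted
retrocopies are mutated copies of their parent at a controlled protein
identity, which is all the discovery filters act on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import dendropy
import yaml
from scipy import stats

from .genome_model import (
    AnnotationSet,
    ChromosomeInfo,
    GeneModel,
    PHYLO_STAGES,
    StagedTree,
    write_annotation,
)
from .retrocopy_id import A_TO_A, A_TO_X, X_TO_A

__all__ = [
    "PlantedEvent",
    "SimScenario",
    "GroundTruthLedger",
    "simulate_clade",
    "simulate_expression",
    "analytic_ttest_power",
    "write_world",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# minimal codon table for backtranslation (one codon per amino acid)
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_STOP = "TAA"


@dataclass
class PlantedEvent:
    """One retroduplication to plant: direction, age and discoverability."""

    direction: str            # "X->A" | "A->A" | "A->X"
    stage: str                # PS1..PS9
    identity: float = 0.95    # target protein identity to the parent
    decoy: str | None = None  # None | "tandem" | "truncated" | "low_identity"


def _default_events() -> list[PlantedEvent]:
    directions = {
        "PS1": X_TO_A, "PS2": A_TO_A, "PS3": X_TO_A, "PS4": X_TO_A,
        "PS5": X_TO_A, "PS6": A_TO_A, "PS7": X_TO_A, "PS8": A_TO_X,
        "PS9": A_TO_A,
    }
    return [PlantedEvent(directions[ps], ps) for ps in PHYLO_STAGES]


def _default_species() -> dict[str, str]:
    # one species per stage PS2..PS9 plus two extra lineages and an outgroup
    layout = {f"s{i:02d}": f"PS{i}" for i in range(2, 10)}
    layout["s02b"] = "PS2"
    layout["s05b"] = "PS5"
    layout["outg"] = "outgroup"
    return layout


@dataclass
class SimScenario:
    """Fully specified study conditions for one synthetic world.

    Defaults: a 12-species clade (focal + 10 staged ingroup species + 1
    outgroup), one X-like chromosome and two autosomes, 300 background
    genes, nine planted events (one per stage), three decoys, 2-fold
    sex-bias effects with sigma 0.5 on the log2 scale and 4 replicates per
    group.
    """

    seed: int = 0
    focal_species: str = "focal"
    species_stages: dict[str, str] = field(default_factory=_default_species)
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {"X": 2_000_000, "2": 3_000_000, "3": 3_000_000}
    )
    x_chromosome: str = "X"
    n_background_genes: int = 300
    planted_events: list[PlantedEvent] = field(default_factory=_default_events)
    plant_decoys: bool = True
    # expression parameters
    effect_log2: float = 1.0       # |log2 fold change| of a biased gene
    sigma: float = 0.5             # replicate noise sd (log2 scale)
    n_reps: int = 4                # replicates per sample group
    stage_sigma: float = 0.3       # noise sd of stage series (ln(FPKM+1) scale)

    def __post_init__(self) -> None:
        for ev in self.planted_events:
            if ev.stage not in PHYLO_STAGES:
                raise ValueError(f"unknown stage {ev.stage!r}")
            if ev.decoy is None and ev.identity < 0.3:
                import warnings

                warnings.warn(
                    f"planted event at {ev.stage} has identity {ev.identity} "
                    "< 0.30 and is undiscoverable by design"
                )

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "seed": self.seed,
            "focal_species": self.focal_species,
            "species_stages": self.species_stages,
            "chromosome_lengths": self.chromosome_lengths,
            "x_chromosome": self.x_chromosome,
            "n_background_genes": self.n_background_genes,
            "planted_events": [
                {
                    "direction": e.direction,
                    "stage": e.stage,
                    "identity": e.identity,
                    "decoy": e.decoy,
                }
                for e in self.planted_events
            ],
            "plant_decoys": self.plant_decoys,
            "effect_log2": self.effect_log2,
            "sigma": self.sigma,
            "n_reps": self.n_reps,
            "stage_sigma": self.stage_sigma,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimScenario":
        data = yaml.safe_load(Path(path).read_text())
        events = [PlantedEvent(**e) for e in data.pop("planted_events", [])]
        return cls(planted_events=events or _default_events(), **data)


@dataclass
class LedgerEvent:
    parent_base: str
    retro_base: str
    parent_id: str  # focal-species ids
    retro_id: str
    direction: str
    stage: str
    decoy: str  # "none" or decoy class


@dataclass
class GroundTruthLedger:
    """What was planted: events plus per-gene expression truth labels."""

    events: list[LedgerEvent] = field(default_factory=list)
    bias_truth: dict[str, str] = field(default_factory=dict)      # gene -> label
    profile_truth: dict[str, str] = field(default_factory=dict)   # gene -> class

    def real_events(self) -> list[LedgerEvent]:
        return [e for e in self.events if e.decoy == "none"]

    def decoy_events(self) -> list[LedgerEvent]:
        return [e for e in self.events if e.decoy != "none"]

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parent_id": e.parent_id,
                    "retro_id": e.retro_id,
                    "direction": e.direction,
                    "stage": e.stage,
                    "decoy": e.decoy,
                }
                for e in self.events
            ]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.events_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene template machinery
# ---------------------------------------------------------------------------


@dataclass
class _GeneTemplate:
    base: str
    chromosome: str
    strand: str
    protein: str
    cds: str
    exon_lengths: list[int]    # transcription order, bp; sums to len(cds)
    intron_lengths: list[int]  # len = exons - 1
    intergap: int              # gap preceding this gene on the chromosome


def _random_protein(rng: np.random.Generator, length: int) -> str:
    aa = rng.choice(list(AMINO_ACIDS), size=length)
    return "M" + "".join(aa[1:])


def _backtranslate(protein: str) -> str:
    return "".join(_CODON[a] for a in protein) + _STOP


def _split_cds(rng: np.random.Generator, cds_len: int, n_exons: int) -> list[int]:
    """Exon lengths (bp) summing to cds_len, each >= 60 bp."""
    if n_exons == 1:
        return [cds_len]
    while True:
        cuts = np.sort(rng.integers(60, cds_len - 60, size=n_exons - 1))
        lengths = np.diff(np.concatenate([[0], cuts, [cds_len]]))
        if (lengths >= 60).all():
            return [int(x) for x in lengths]


def _make_background(
    rng: np.random.Generator, scenario: SimScenario
) -> dict[str, list[_GeneTemplate]]:
    """Background gene templates per chromosome, shared by all species."""
    chroms = list(scenario.chromosome_lengths)
    weights = np.array([scenario.chromosome_lengths[c] for c in chroms], float)
    weights /= weights.sum()
    per_chrom: dict[str, list[_GeneTemplate]] = {c: [] for c in chroms}
    for i in range(scenario.n_background_genes):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        protein = _random_protein(rng, int(rng.integers(140, 300)))
        cds = _backtranslate(protein)
        n_exons = int(rng.integers(2, 7))
        exon_lengths = _split_cds(rng, len(cds), n_exons)
        intron_lengths = [int(rng.integers(60, 500)) for _ in range(n_exons - 1)]
        per_chrom[chrom].append(
            _GeneTemplate(
                base=f"g{i:04d}",
                chromosome=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                protein=protein,
                cds=cds,
                exon_lengths=exon_lengths,
                intron_lengths=intron_lengths,
                intergap=int(rng.integers(200, 2000)),
            )
        )
    return per_chrom


def _mutate_to_identity(
    rng: np.random.Generator, protein: str, identity: float
) -> str:
    """Substitute amino acids to reach the target protein identity."""
    n_mut = int(round((1.0 - identity) * len(protein)))
    if n_mut == 0:
        return protein
    positions = rng.choice(np.arange(1, len(protein)), size=min(n_mut, len(protein) - 1), replace=False)
    seq = list(protein)
    for p in positions:
        choices = [a for a in AMINO_ACIDS if a != seq[p]]
        seq[p] = choices[int(rng.integers(len(choices)))]
    return "".join(seq)


def _retro_template(
    rng: np.random.Generator, parent: _GeneTemplate, base: str, chrom: str,
    identity: float, decoy: str | None,
) -> _GeneTemplate:
    if decoy == "truncated":
        protein = parent.protein[: int(0.6 * len(parent.protein))]
    elif decoy == "low_identity":
        protein = _mutate_to_identity(rng, parent.protein, 0.25)
    else:
        protein = _mutate_to_identity(rng, parent.protein, identity)
    cds = _backtranslate(protein)
    if decoy == "tandem":
        # structural copy retaining introns, same chromosome as parent
        protein = _mutate_to_identity(rng, parent.protein, identity)
        cds = _backtranslate(protein)
        return _GeneTemplate(
            base=base,
            chromosome=parent.chromosome,
            strand=parent.strand,
            protein=protein,
            cds=cds,
            exon_lengths=_split_cds(rng, len(cds), len(parent.exon_lengths)),
            intron_lengths=list(parent.intron_lengths),
            intergap=int(rng.integers(200, 2000)),
        )
    return _GeneTemplate(
        base=base,
        chromosome=chrom,
        strand="+" if rng.random() < 0.5 else "-",
        protein=protein,
        cds=cds,
        exon_lengths=[len(cds)],
        intron_lengths=[],
        intergap=int(rng.integers(200, 2000)),
    )


def _autosomes(scenario: SimScenario) -> list[str]:
    return [c for c in scenario.chromosome_lengths if c != scenario.x_chromosome]


def _event_chromosomes(
    rng: np.random.Generator, scenario: SimScenario, direction: str
) -> tuple[str, str]:
    autos = _autosomes(scenario)
    x = scenario.x_chromosome
    if direction == X_TO_A:
        return x, autos[int(rng.integers(len(autos)))]
    if direction == A_TO_X:
        return autos[int(rng.integers(len(autos)))], x
    src, dst = rng.choice(len(autos), size=2, replace=False)
    return autos[src], autos[dst]


def _build_annotation(
    species: str,
    scenario: SimScenario,
    layout: Mapping[str, list[_GeneTemplate]],
) -> AnnotationSet:
    """Lay the ordered gene templates of each chromosome onto coordinates."""
    genes: dict[str, GeneModel] = {}
    chroms: dict[str, ChromosomeInfo] = {}
    for chrom, templates in layout.items():
        cursor = 1000
        for t in templates:
            cursor += t.intergap
            start = cursor
            exons_genomic: list[tuple[int, int]] = []
            lengths = t.exon_lengths
            introns = t.intron_lengths
            if t.strand == "-":
                lengths = lengths[::-1]
                introns = introns[::-1]
            pos = start
            for i, ln in enumerate(lengths):
                exons_genomic.append((pos, pos + ln))
                pos += ln
                if i < len(introns):
                    pos += introns[i]
            end = pos
            exons = exons_genomic[::-1] if t.strand == "-" else exons_genomic
            gid = f"{species}_{t.base}"
            genes[gid] = GeneModel(
                gene_id=gid,
                species_id=species,
                chromosome=chrom,
                strand=t.strand,
                start=start,
                end=end,
                exons=exons,
                protein=t.protein,
                cds=t.cds,
            )
            cursor = end
        length = max(scenario.chromosome_lengths[chrom], cursor + 10_000)
        chroms[chrom] = ChromosomeInfo(
            name=chrom,
            sex_class="X_like" if chrom == scenario.x_chromosome else "autosome",
            length=length,
        )
    return AnnotationSet(species_id=species, genes=genes, chromosomes=chroms)


def simulate_clade(
    scenario: SimScenario,
) -> tuple[dict[str, AnnotationSet], StagedTree, GroundTruthLedger]:
    """Generate the annotated clade with planted events and decoys.

    A retrocopy planted at stage PSk is an intronless, identity-controlled
    copy of its parent inserted at the same background position (so flanking
    order is conserved) in the focal species and every ingroup species whose
    stage index is <= k; it is absent elsewhere.  Decoys (tandem
    intron-retaining duplicate, truncated copy, 25%-identity homolog) are
    planted only in the focal species.
    """
    rng = np.random.default_rng(scenario.seed)
    background = _make_background(rng, scenario)
    ledger = GroundTruthLedger()

    stage_idx = {sp: (PHYLO_STAGES.index(st) + 1 if st != "outgroup" else None)
                 for sp, st in scenario.species_stages.items()}

    # choose parents and insertion slots (template-level, shared by species)
    used_parents: set[str] = set()
    plants = []  # (event, parent_template, retro_template, slot index)
    slots_taken: dict[str, set[int]] = {c: set() for c in background}
    events = list(scenario.planted_events)
    if scenario.plant_decoys:
        events += [
            PlantedEvent(X_TO_A, "PS1", identity=0.95, decoy="tandem"),
            PlantedEvent(X_TO_A, "PS1", identity=0.95, decoy="truncated"),
            PlantedEvent(X_TO_A, "PS1", identity=0.95, decoy="low_identity"),
        ]
    for k, ev in enumerate(events):
        src, dst = _event_chromosomes(rng, scenario, ev.direction)
        eligible = [
            t
            for t in background[src]
            if len(t.exon_lengths) >= 3
            and t.base not in used_parents
            and len(t.protein) >= 150
        ]
        parent = eligible[int(rng.integers(len(eligible)))]
        used_parents.add(parent.base)
        base = f"retro{k:02d}" if ev.decoy is None else f"decoy{k:02d}"
        retro = _retro_template(rng, parent, base, dst, ev.identity, ev.decoy)
        target_chrom = retro.chromosome
        # spaced insertion slots keep planted neighborhoods independent
        n_bg = len(background[target_chrom])
        slot = None
        for cand in rng.permutation(n_bg - 1):
            if all(abs(cand - s) > 2 for s in slots_taken[target_chrom]):
                slot = int(cand) + 1
                break
        slots_taken[target_chrom].add(slot - 1)
        plants.append((ev, parent, retro, slot))

    # per-species chromosome layouts
    annotations: dict[str, AnnotationSet] = {}
    all_species = [scenario.focal_species] + sorted(scenario.species_stages)
    for sp in all_species:
        idx = 1 if sp == scenario.focal_species else stage_idx[sp]
        layout: dict[str, list[_GeneTemplate]] = {}
        for chrom, templates in background.items():
            inserts: dict[int, list[_GeneTemplate]] = {}
            for ev, parent, retro, slot in plants:
                if retro.chromosome != chrom:
                    continue
                if ev.decoy is not None:
                    carried = sp == scenario.focal_species
                else:
                    carried = idx is not None and idx <= PHYLO_STAGES.index(ev.stage) + 1
                if carried:
                    inserts.setdefault(slot, []).append(retro)
            ordered: list[_GeneTemplate] = []
            for i, t in enumerate(templates):
                ordered.append(t)
                for r in inserts.get(i + 1, []):
                    ordered.append(r)
            layout[chrom] = ordered
        annotations[sp] = _build_annotation(sp, scenario, layout)

    # ledger rows reference focal-species ids
    focal = scenario.focal_species
    for ev, parent, retro, _slot in plants:
        ledger.events.append(
            LedgerEvent(
                parent_base=parent.base,
                retro_base=retro.base,
                parent_id=f"{focal}_{parent.base}",
                retro_id=f"{focal}_{retro.base}",
                direction=ev.direction,
                stage=ev.stage,
                decoy=ev.decoy or "none",
            )
        )

    tree = _build_tree(scenario)
    return annotations, tree, ledger


def _build_tree(scenario: SimScenario) -> StagedTree:
    """Ladder tree: each stage's species form a clade attaching successively
    rootward along the focal path; the outgroup is sister to everything."""
    by_stage: dict[str, list[str]] = {}
    outgroups: list[str] = []
    for sp, st in scenario.species_stages.items():
        (outgroups if st == "outgroup" else by_stage.setdefault(st, [])).append(sp)
    newick = scenario.focal_species
    for ps in PHYLO_STAGES[1:]:
        members = sorted(by_stage.get(ps, []))
        if not members:
            continue
        clade = members[0] if len(members) == 1 else "(" + ",".join(members) + ")"
        newick = f"({newick},{clade})"
    for og in sorted(outgroups):
        newick = f"({newick},{og})"
    tree = dendropy.Tree.get(data=newick + ";", schema="newick")
    return StagedTree(
        topology=tree,
        focal_species=scenario.focal_species,
        stage_of_species=dict(scenario.species_stages),
    )


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

# noiseless stage trajectories on the ln(FPKM+1) scale
_TRAJ_PARENT_MSCI = (2.5, 1.8, 1.2, 0.8)   # X-linked parent silenced in meiosis
_TRAJ_RETRO_RISING = (0.8, 1.4, 1.9, 2.4)  # autosomal retrocopy escaping MSCI
_TRAJ_FLAT = (1.5, 1.5, 1.5, 1.5)

from .expression_analysis import ExpressionMatrix, SPERMATOGENESIS_STAGES


def _assign_truth(scenario: SimScenario, ledger: GroundTruthLedger,
                  focal_genes: list[str]) -> None:
    """Bias/profile truth labels mirroring the study's observed motifs."""
    young = {f"PS{i}" for i in range(1, 8)}
    for ev in ledger.real_events():
        if ev.direction == X_TO_A and ev.stage in young:
            ledger.bias_truth[ev.retro_id] = "male"
            ledger.bias_truth[ev.parent_id] = "female"
            ledger.profile_truth[ev.retro_id] = "later_stage_max"
            ledger.profile_truth[ev.parent_id] = "premeiotic_max"
        else:
            ledger.bias_truth[ev.retro_id] = "female"
            ledger.bias_truth[ev.parent_id] = "unbiased"
    for g in focal_genes:
        ledger.bias_truth.setdefault(g, "unbiased")


def simulate_expression(
    scenario: SimScenario,
    ledger: GroundTruthLedger,
    focal_ann: AnnotationSet,
    rng: np.random.Generator | None = None,
) -> dict[str, ExpressionMatrix]:
    """Microarray, bulk RNA-seq and spermatogenesis-stage matrices for the
    focal species, with truth labels written into the ledger.

    Sex-biased genes get +/- effect_log2/2 shifts around a per-gene baseline
    with Normal(0, sigma) replicate noise; TPM matrices are 2**value so the
    bias acts multiplicatively; stage series follow the MSCI trajectories
    with Normal(0, stage_sigma) noise truncated at zero.
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.seed + 1)
    genes = sorted(focal_ann.genes)
    _assign_truth(scenario, ledger, genes)
    n = scenario.n_reps
    eff = scenario.effect_log2

    def shifted(truth: str, base: float) -> tuple[float, float]:
        if truth == "male":
            return base + eff / 2, base - eff / 2
        if truth == "female":
            return base - eff / 2, base + eff / 2
        return base, base

    base = rng.uniform(4, 10, size=len(genes))

    # microarray (log2 RMA scale): testis vs ovary
    ma_samples = [f"testis_{i+1}" for i in range(n)] + [f"ovary_{i+1}" for i in range(n)]
    ma_groups = {s: ("testis" if s.startswith("testis") else "ovary") for s in ma_samples}
    ma = np.empty((len(genes), 2 * n))
    for i, g in enumerate(genes):
        m_mean, f_mean = shifted(ledger.bias_truth[g], base[i])
        ma[i, :n] = m_mean + rng.normal(0, scenario.sigma, n)
        ma[i, n:] = f_mean + rng.normal(0, scenario.sigma, n)
    microarray = ExpressionMatrix(
        "microarray_log2RMA", pd.DataFrame(ma, index=genes, columns=ma_samples), ma_groups
    )

    # bulk RNA-seq (TPM): male vs female reproductive organs
    rs_samples = [f"male_repro_{i+1}" for i in range(n)] + [
        f"female_repro_{i+1}" for i in range(n)
    ]
    rs_groups = {
        s: ("male_repro" if s.startswith("male") else "female_repro") for s in rs_samples
    }
    rs = np.empty((len(genes), 2 * n))
    for i, g in enumerate(genes):
        m_mean, f_mean = shifted(ledger.bias_truth[g], base[i] - 2.0)
        rs[i, :n] = 2.0 ** (m_mean + rng.normal(0, scenario.sigma, n))
        rs[i, n:] = 2.0 ** (f_mean + rng.normal(0, scenario.sigma, n))
    rnaseq = ExpressionMatrix(
        "rnaseq_TPM", pd.DataFrame(rs, index=genes, columns=rs_samples), rs_groups
    )

    # spermatogenesis stage series (FPKM)
    st_samples = [f"{g}_{i+1}" for g in SPERMATOGENESIS_STAGES for i in range(n)]
    st_groups = {s: s.rsplit("_", 1)[0] for s in st_samples}
    fpkm = np.empty((len(genes), 4 * n))
    for i, g in enumerate(genes):
        traj = {
            "later_stage_max": _TRAJ_RETRO_RISING,
            "premeiotic_max": _TRAJ_PARENT_MSCI,
        }.get(ledger.profile_truth.get(g, ""), _TRAJ_FLAT)
        for j, mu in enumerate(traj):
            v = np.maximum(0.0, mu + rng.normal(0, scenario.stage_sigma, n))
            fpkm[i, j * n : (j + 1) * n] = np.expm1(v)
    stage = ExpressionMatrix(
        "stage_FPKM",
        pd.DataFrame(np.log1p(fpkm), index=genes, columns=st_samples),
        st_groups,
    )
    return {"microarray": microarray, "rnaseq": rnaseq, "stage": stage}


def analytic_ttest_power(
    delta: float, sigma: float, n: int, alpha: float = 0.05
) -> float:
    """Closed-form power of the two-sided two-sample equal-variance t test
    with effect ``delta``, noise sd ``sigma`` and ``n`` replicates/group."""
    df = 2 * n - 2
    ncp = delta / (sigma * np.sqrt(2.0 / n))
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    return float(
        1 - stats.nct.cdf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp)
    )


def write_world(
    outdir: str | Path,
    annotations: Mapping[str, AnnotationSet],
    tree: StagedTree,
    ledger: GroundTruthLedger,
    expression: Mapping[str, ExpressionMatrix] | None = None,
    scenario: SimScenario | None = None,
) -> None:
    """Write the whole world in the on-disk formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp, ann in annotations.items():
        write_annotation(ann, outdir / sp)
    tree.write(outdir / "species.nwk", outdir / "stages.tsv")
    ledger.write_tsv(outdir / "ledger.tsv")
    from .synteny_dating import OrthologMap

    OrthologMap.from_shared_basenames(dict(annotations)).write_tsv(
        outdir / "orthologs.tsv"
    )
    if expression:
        for name, m in expression.items():
            m.write_tsv(outdir / f"expr_{name}.tsv", outdir / f"expr_{name}.samples.tsv")
    if scenario is not None:
        scenario.to_yaml(outdir / "scenario.yaml")
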