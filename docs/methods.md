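# Methods

This note documents the models and procedures implemented in `retrotraffic`,
the parameters that matter, the design choices made where the method left
room, and what the synthetic-data generator does and does not emulate.

## Gene models and coordinates

Annotations are read from GFF3 (gene/mRNA/exon/CDS) with protein and CDS
FASTA keyed by mRNA id. GFF3 is 1-based inclusive on disk; the in-memory
model is 0-based half-open, and the readers/writers are the only conversion
point. For multi-transcript genes the longest-protein isoform represents the
gene (ties broken by lexicographic mRNA id) — the choice is deterministic and
documented rather than inherited from any upstream convention. Exons are
stored in transcription order, so "first exon" is biological on both strands.
Genes on chromosomes without metadata (unplaced scaffolds) are retained for
alignment search but excluded from gene order and traffic statistics, since
direction classes need a chromosome identity. An intron is the gap between
genomically adjacent exons; `longest_intron` is 0 for single-exon genes.

## Retrocopy discovery

Candidate paralogs come from local protein alignment: affine-gap
Smith–Waterman with BLOSUM62, gap open 11 / extend 1 (a length-L gap costs
11 + L, the BLAST convention), via Bio.Align.PairwiseAligner. Identity is
identities divided by alignment columns (gaps included); coverage of each
gene is its aligned span over its full protein length — the full-length
denominator makes the reciprocal > 70% rule a genuine length filter. The
discovery thresholds are identity > 0.30 and reciprocal coverage > 0.70.

All-vs-all alignment is preceded by a seeding prefilter: only pairs sharing
at least two distinct 5-mers are aligned. Two unrelated proteins of typical
length share ~0.01 5-mers in expectation, while any pair near the 30%
identity threshold shares many, so the filter is effectively lossless at a
large constant-factor speedup; it can be disabled in
`IdentificationConfig(use_seed_prefilter=False)`.

Intron-loss evidence: a parental exon–exon junction is *supported* when it
falls inside a single gapless aligned block with at least 10 aa
(`junction_flank_bp` = 30 bp) aligned on both sides, and the retrogene has no
exon junction at the mapped residue (a retained intron at that position
voids that junction, not the pair). A junction that splits a codon belongs
to the residue containing it. A pair needs ≥ 1 supported junction.

Parent assignment: more introns wins. If the putative parent's introns are
all shorter than 50 bp — the classic mis-assignment signature — or exon
counts tie, the gene with strictly more cross-species synteny conservation
is the parent; unresolved pairs are dropped with a warning. If a retrogene
matches several parents, the highest-identity pair is kept (ties: longest
parent protein). Direction classes X→A, A→A (distinct autosomes), A→X use
whole chromosomes: arms 2R/2L and 3R/3L collapse to chromosomes 2 and 3, and
same-arm-group pairs are treated as intrachromosomal and excluded.

## Synteny dating

The species tree's focal root path is cut into stages PS1 (most recent) …
PS9. Each non-focal species carries the label of the path segment
immediately rootward of its attachment node: a retrocopy dated PSk is
expected in the focal species and every ingroup species with stage index
≤ k. The stage call is the maximum stage among species where the retrogene
is present *and* syntenic; presence alone never advances the call, and a
retrogene found only in the focal species is PS1. Outgroup species only
confirm absence beyond the called stage.

"Conserved gene order" is implemented strictly: a flanking gene within
±10 genes (`flank_window`) counts as conserved when its ortholog sits at the
same signed offset from the retrogene's ortholog on the same chromosome, and
≥ 2 such neighbors (`min_conserved_neighbors`) are required. Orientation is
ignored — order, not strand, is the criterion. This exact-offset rule is the
most conservative deterministic reading of "at least two genes with a
conserved gene order"; looser rules (e.g. longest order-preserving
subsequence) pass randomly shuffled neighborhoods too easily. Orthology is
taken from an input table (reciprocal-best-hit or curated); the package does
not infer orthology. In synthetic worlds orthology is by shared gene
basename.

Stage groups for the traffic analysis: young = PS1–7 (lineages with
heteromorphic sex chromosomes), old = PS8–9 (homomorphic), with a finer
PS1–4 / PS5–7 split of the young group.

## Traffic expectation model

The expected share of each movement direction comes from weighting every
ordered interchromosomal pair (s, t):

    w(s → t) = G_s · D_s · A_t · F_t

- `G_s` — source gene count (more genes, more source mRNA species);
- `D_s` — per-gene dosage weight; the *An. gambiae* X is dosage-compensated,
  so `D_X = 1.0` by default;
- `A_t` — target insertion opportunity, proportional to chromosome length by
  default (switchable to gene count);
- `F_t` — fixation weight from relative effective population size:
  `F_X = 0.75`, autosomes 1.0.

Direction frequencies are normalized sums over the X→A, A→A (distinct
autosomes) and A→X pair classes; they sum to 1 and are invariant to uniform
rescaling of any weight family. The published expected percentages for any
particular genome depend on that genome's gene counts and lengths, so the
model is fully parameterized configuration, not constants.

Excess rate per direction: `100 · (observed share − expected share) /
expected share`; a direction with zero expectation and nonzero observation
is reported as NaN with a warning.

### Permutation χ² test

Significance of an observed count vector is assessed by Monte-Carlo
goodness-of-fit: `n_perm` multinomial replicates of the observed total drawn
under the expected frequencies, Pearson χ² against the expected numbers, and
the add-one estimate `p = (1 + #{stat ≥ observed}) / (n_perm + 1)` — valid
(conservative) under ties and never below `1/(n_perm+1)`. Because the
statistic is discrete, the add-one p is super-uniform under the null; for
calibration checks the `smooth=True` variant returns the standard randomized
tie-broken estimator, which is exactly Uniform(0,1) under the null. The
published description of the original permutation scheme is not
algorithmically explicit; this package implements the standard Monte-Carlo
goodness-of-fit reading, and its p-values are not expected to reproduce any
particular published permutation p exactly.

2×2 association uses the cross-product odds ratio (Haldane–Anscombe +0.5 on
zero cells, with a warning), the Woolf interval
`exp(ln OR ± z·sqrt(1/a + 1/b + 1/c + 1/d))`, and the two-sided Fisher exact
test (hypergeometric probability-mass rule). No multiple-testing correction
is applied anywhere; all p-values are raw.

## Expression analysis

Normalization is platform-specific: microarray log2 RMA values pass through
(they arrive normalized); RNA-seq TPM gets the 10⁻³ offset; spermatogenesis
FPKM becomes ln(FPKM + 1) per sample, with group means taken downstream.

Sex bias is a per-gene two-tailed Student's t test (equal variances, as
stated — not Welch) between male and female reproductive-organ samples at
α = 0.05: male if significant with higher male mean, female if the reverse,
unbiased otherwise; genes missing from a platform or with < 2 replicates per
group are `no_data`. Microarray and RNA-seq calls are kept separate and may
disagree; no reconciliation rule is invented.

A stage profile over premeiotic / meiosis I / meiosis II / postmeiotic means
is `later_stage_max` when the best post-premeiotic mean strictly exceeds the
premeiotic mean (ties → `premeiotic_max`; the rule is invariant to any
monotone transform of the four means). Rising profiles in autosomal
retrogenes against falling X-linked parents is the MSCI escape signature.

Paired comparisons use the Wilcoxon signed-rank test (zero differences
dropped; exact null for n ≤ 25 without ties, continuity-corrected normal
approximation otherwise; one- or two-tailed). `crosstab_report` assembles the
bias × age, bias × direction (young), and bias × profile 2×2 tables with
odds ratio, Woolf CI and Fisher p attached.

## Synthetic worlds

`SimScenario` defaults define the study conditions: 12 species (focal + one
or two lineages per stage PS2–PS9 + outgroup) on a ladder tree, one X-like
chromosome (2 Mb) and two autosomes (3 Mb each), 300 background genes of
2–6 exons with random proteins of 140–300 aa, nine planted events (one per
stage, mixed directions) at 95% protein identity, and three decoys: a tandem
intron-retaining duplicate (same chromosome), a truncated 60% copy, and a
25%-identity homolog. A retrocopy planted at PSk is inserted intronless at
the same background slot — hence with perfectly conserved flanks — in every
carrier species and absent elsewhere; insertion slots are spaced so planted
neighborhoods never interact. Identity targets are hit by substituting amino
acids (and their codons), so protein identity — the quantity the filters act
on — is controlled directly.

Expression defaults: 4 replicates per group, |log2 fold| = 1 effects with
σ = 0.5 replicate noise for biased genes (young X→A retrogenes male-biased,
their parents female-biased, mirroring the observed motif), and stage
trajectories on the ln(FPKM+1) scale — parents (2.5, 1.8, 1.2, 0.8)
declining, escaping retrocopies (0.8, 1.4, 1.9, 2.4) rising, σ = 0.3 — with
`analytic_ttest_power` providing the closed-form noncentral-t reference for
the caller's power.

What the generator does *not* emulate: sequence divergence between species,
codon models, indels, selection, annotation errors, expression count noise
(values are Gaussian on the log scale, not negative-binomial), and real
orthology inference. Passing tests on synthetic worlds therefore validate
the pipeline's logic — filters, dating, bookkeeping, statistics — not its
robustness to noisy annotations or distant homology.

## Numerical and size choices

Default problem sizes (300 background genes, 12 species, 9 plants) keep a
full end-to-end run under a few seconds; calibration simulations use 1500 to
2000 genes/trials, enough for binomial 99% bounds of a few tenths of a
percent. Chi-square tie comparison uses a 1e-9 tolerance; alignment of
sequences with no positive-scoring local alignment yields zero
identity/coverage. All randomness flows from a single integer seed through
`numpy.random.default_rng`.

## Known limitations

- Discovery is protein-level only; DNA-level duplicates and intrachromosomal
  retrocopies are out of scope by design.
- The exact-offset synteny rule is conservative: a single gene insertion
  between a flank gene and the focal locus in one species voids that
  neighbor (others on either side still count).
- The expectation model reproduces published expected shares only when fed
  the same per-chromosome inputs; those inputs are configuration.
- The permutation test is a standard Monte-Carlo goodness-of-fit test; see
  above for why published permutation p-values from differently specified
  schemes are not reproduction targets.
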