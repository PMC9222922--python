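"""Expected interchromosomal gene-traffic frequencies, excess rates and
significance tests for the out-of-the-X pattern.

The expectation model assigns each ordered chromosome pair (s, t), s != t by
arm group, the weight

    w(s -> t) = G_s * D_s * A_t * F_t

where G_s is the source gene count, D_s the per-gene mRNA dosage (X-linked
dosage compensation => D_X = 1 by default), A_t the insertion opportunity of
the target (proportional to chromosome length by default) and F_t the
fixation weight (relative effective population size: 0.75 for the X, 1 for
autosomes).  Direction frequencies are normalized sums of these weights over
the X->A, A->A (distinct autosomes) and A->X pair classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genome_model import AnnotationSet

__all__ = [
    "MovementCounts",
    "ChromosomeWeights",
    "ExpectationModel",
    "TrafficResult",
    "expected_frequencies",
    "excess_rate",
    "permutation_chisq",
    "odds_ratio",
    "woolf_ci",
    "fisher_exact",
]

X_TO_A = "X->A"
A_TO_A = "A->A"
A_TO_X = "A->X"
DIRECTIONS = (X_TO_A, A_TO_A, A_TO_X)


@dataclass
class MovementCounts:
    """Observed interchromosomal movement counts for one stage group."""

    n_xa: int = 0
    n_aa: int = 0
    n_ax: int = 0

    @property
    def n_total(self) -> int:
        return self.n_xa + self.n_aa + self.n_ax

    def add(self, direction: str) -> None:
        if direction == X_TO_A:
            self.n_xa += 1
        elif direction == A_TO_A:
            self.n_aa += 1
        elif direction == A_TO_X:
            self.n_ax += 1
        else:
            raise ValueError(f"unknown direction {direction!r}")

    def as_dict(self) -> dict[str, int]:
        return {X_TO_A: self.n_xa, A_TO_A: self.n_aa, A_TO_X: self.n_ax}

    def shares(self) -> dict[str, float]:
        n = self.n_total
        if n == 0:
            raise ValueError("no observed movements")
        return {d: c / n for d, c in self.as_dict().items()}


@dataclass
class ChromosomeWeights:
    """Per-chromosome inputs of the expectation model."""

    name: str
    sex_class: str          # "X_like" | "autosome"
    gene_count: float       # G
    dosage: float = 1.0     # D, source-side mRNA weight
    insertion: float = 1.0  # A, target-side opportunity
    fixation: float = 1.0   # F, target-side fixation weight
    arm_group: str = ""

    def __post_init__(self) -> None:
        if min(self.dosage, self.insertion, self.fixation) <= 0:
            raise ValueError(f"{self.name}: weights must be > 0")
        if not self.arm_group:
            self.arm_group = self.name


@dataclass
class ExpectationModel:
    chromosomes: list[ChromosomeWeights]

    def __post_init__(self) -> None:
        if len(self.chromosomes) < 2:
            raise ValueError("expectation model needs at least two chromosomes")
        n_x = sum(c.sex_class == "X_like" for c in self.chromosomes)
        n_a = sum(c.sex_class == "autosome" for c in self.chromosomes)
        if n_x != 1 or n_a < 2:
            raise ValueError("model requires exactly one X-like and >= 2 autosomes")

    @classmethod
    def from_annotation(
        cls,
        ann: AnnotationSet,
        d_x: float = 1.0,
        f_x: float = 0.75,
        insertion: str = "length",
    ) -> "ExpectationModel":
        """Model parameterized from an annotation set.

        ``insertion`` selects the target-opportunity convention: chromosome
        "length" (default) or "gene_count".
        """
        chroms = []
        for c in ann.chromosomes.values():
            is_x = c.sex_class == "X_like"
            chroms.append(
                ChromosomeWeights(
                    name=c.name,
                    sex_class=c.sex_class,
                    gene_count=c.gene_count,
                    dosage=d_x if is_x else 1.0,
                    insertion=float(c.length if insertion == "length" else c.gene_count),
                    fixation=f_x if is_x else 1.0,
                    arm_group=c.arm_group,
                )
            )
        return cls(chroms)

    def expected_frequencies(self) -> dict[str, float]:
        return expected_frequencies(self)


def expected_frequencies(model: ExpectationModel) -> dict[str, float]:
    """Normalized expected movement frequencies per direction class."""
    totals = dict.fromkeys(DIRECTIONS, 0.0)
    for src in model.chromosomes:
        for dst in model.chromosomes:
            if src.arm_group == dst.arm_group:
                continue
            w = src.gene_count * src.dosage * dst.insertion * dst.fixation
            if src.sex_class == "X_like":
                totals[X_TO_A] += w
            elif dst.sex_class == "X_like":
                totals[A_TO_X] += w
            else:
                totals[A_TO_A] += w
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("all movement weights are zero")
    return {d: v / grand for d, v in totals.items()}


def excess_rate(
    observed: MovementCounts, expected_freq: Mapping[str, float]
) -> dict[str, float]:
    """Percent excess (positive) or deficit (negative) of each direction:
    100 * (observed_share - expected_share) / expected_share.

    NaN (with a warning) when a direction has zero expectation but nonzero
    observation.
    """
    shares = observed.shares()
    out = {}
    for d in DIRECTIONS:
        exp = expected_freq[d]
        if exp == 0:
            if shares[d] > 0:
                warnings.warn(f"{d}: expected share is 0 with observations; NA")
                out[d] = float("nan")
            else:
                out[d] = 0.0
        else:
            out[d] = 100.0 * (shares[d] - exp) / exp
    return out


def permutation_chisq(
    observed: MovementCounts,
    expected_freq: Mapping[str, float],
    n_perm: int = 1_000_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    smooth: bool = False,
) -> float:
    """Monte-Carlo goodness-of-fit test of observed counts vs expectation.

    ``n_perm`` multinomial replicates of size n_total are drawn under the
    expected frequencies; the statistic is the Pearson chi-square against
    the expected numbers; p = (1 + #{replicate stat >= observed}) /
    (n_perm + 1), so p is never below 1/(n_perm+1) and is conservatively
    valid even with ties in the discrete statistic.

    ``smooth=True`` instead returns the randomized (tie-broken) estimator
    p = (#{stat > observed} + U * (1 + #{stat == observed})) / (n_perm + 1),
    which is exactly Uniform(0,1) under the null — the right variant for
    calibration checks, at the cost of an extra random draw.
    """
    if observed.n_total == 0:
        raise ValueError("no observed movements")
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = observed.n_total
    probs = np.array([expected_freq[d] for d in DIRECTIONS], dtype=float)
    probs = probs / probs.sum()
    expected_n = probs * n
    obs = np.array([observed.n_xa, observed.n_aa, observed.n_ax], dtype=float)
    obs_stat = float(np.sum((obs - expected_n) ** 2 / expected_n))
    greater = 0
    equal = 0
    chunk = 200_000
    remaining = n_perm
    while remaining > 0:
        m = min(chunk, remaining)
        sim = rng.multinomial(n, probs, size=m)
        stat = ((sim - expected_n) ** 2 / expected_n).sum(axis=1)
        greater += int(np.count_nonzero(stat > obs_stat + 1e-9))
        equal += int(np.count_nonzero(np.abs(stat - obs_stat) <= 1e-9))
        remaining -= m
    if smooth:
        return float((greater + rng.random() * (1 + equal)) / (n_perm + 1))
    return (1 + greater + equal) / (n_perm + 1)


@dataclass
class TrafficResult:
    """Expected frequencies/numbers, excess rates and permutation p for one
    observed count vector."""

    observed: MovementCounts
    expected_freq: dict[str, float]
    expected_n: dict[str, float]
    excess_pct: dict[str, float]
    p_perm: float
    n_permutations: int

    @classmethod
    def compute(
        cls,
        observed: MovementCounts,
        expected_freq: Mapping[str, float],
        n_perm: int = 1_000_000,
        seed: int | None = None,
        rng: np.random.Generator | None = None,
    ) -> "TrafficResult":
        freq = {d: float(expected_freq[d]) for d in DIRECTIONS}
        total = sum(freq.values())
        freq = {d: v / total for d, v in freq.items()}
        return cls(
            observed=observed,
            expected_freq=freq,
            expected_n={d: v * observed.n_total for d, v in freq.items()},
            excess_pct=excess_rate(observed, freq),
            p_perm=permutation_chisq(observed, freq, n_perm, seed=seed, rng=rng),
            n_permutations=n_perm,
        )

    def as_dict(self) -> dict:
        return {
            "observed": self.observed.as_dict(),
            "expected_freq": self.expected_freq,
            "expected_n": self.expected_n,
            "excess_pct": self.excess_pct,
            "p_perm": self.p_perm,
            "n_permutations": self.n_permutations,
        }


def _corrected(table: Sequence[Sequence[float]]) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("a 2x2 table is required")
    if (t < 0).any():
        raise ValueError("negative cell counts")
    if (t == 0).any():
        warnings.warn("zero cell: Haldane-Anscombe +0.5 correction applied")
        t = t + 0.5
    return t


def odds_ratio(table: Sequence[Sequence[float]]) -> float:
    """(a*d)/(b*c); zero cells get the +0.5 Haldane-Anscombe correction."""
    t = _corrected(table)
    return float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))


def woolf_ci(
    table: Sequence[Sequence[float]], level: float = 0.95
) -> tuple[float, float]:
    """Woolf (log-normal) confidence interval for the odds ratio."""
    t = _corrected(table)
    log_or = np.log(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
    se = np.sqrt((1.0 / t).sum())
    z = stats.norm.ppf(0.5 + level / 2)
    return float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p (hypergeometric probability-mass rule)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("a non-negative 2x2 table is required")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])
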