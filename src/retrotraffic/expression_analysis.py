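"""Sex-biased expression calls, spermatogenesis stage profiles and the group
contingency comparisons built on them.

Platforms: testis/ovary microarray (log2 RMA values, used as given),
reproductive-organ RNA-seq (TPM, offset by 1e-3) and 4-stage spermatogenesis
RNA-seq (FPKM, normalized as ln(FPKM + 1)).  Sex bias is a per-gene
two-tailed Student's t test (equal variances) at p < 0.05, with no
multiple-testing correction.  A gene's stage profile is "later_stage_max"
when its maximum mean expression over meiosis I / meiosis II / postmeiotic
cells strictly exceeds the premeiotic mean — the signature expected of
autosomal retrogenes escaping meiotic sex chromosome inactivation (MSCI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .traffic_stats import fisher_exact, odds_ratio, woolf_ci

__all__ = [
    "ExpressionMatrix",
    "SexBiasCall",
    "StageProfile",
    "CrossTab",
    "normalize",
    "call_sex_bias",
    "call_sex_bias_all",
    "stage_profile",
    "classify_stage_profile",
    "paired_wilcoxon",
    "crosstab_report",
    "SPERMATOGENESIS_STAGES",
]

PLATFORMS = ("microarray_log2RMA", "rnaseq_TPM", "stage_FPKM")
SPERMATOGENESIS_STAGES = ("premeiotic", "meiosis_I", "meiosis_II", "postmeiotic")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix with platform tag and sample grouping."""

    platform: str
    values: pd.DataFrame  # index: gene ids; columns: sample ids
    sample_groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        missing = [c for c in self.values.columns if c not in self.sample_groups]
        if missing:
            raise ValueError(f"ungrouped samples: {missing}")
        if self.platform in ("rnaseq_TPM", "stage_FPKM") and (self.values.values < 0).any():
            raise ValueError("negative abundance values")

    def groups(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            g = self.sample_groups[s]
            if g not in seen:
                seen.append(g)
        return seen

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_groups[s] == group]

    def group_values(self, gene: str, group: str) -> np.ndarray:
        return self.values.loc[gene, self.group_samples(group)].to_numpy(dtype=float)

    def group_means(self, gene: str) -> dict[str, float]:
        return {g: float(np.mean(self.group_values(gene, g))) for g in self.groups()}

    def write_tsv(self, values_path: str | Path, samples_path: str | Path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="gene_id")
        pd.DataFrame(
            {"sample": list(self.sample_groups), "group": list(self.sample_groups.values())}
        ).to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def read_tsv(
        cls, platform: str, values_path: str | Path, samples_path: str | Path
    ) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col="gene_id")
        sheet = pd.read_csv(samples_path, sep="\t")
        return cls(platform, values, dict(zip(sheet["sample"], sheet["group"])))


def normalize(
    raw: pd.DataFrame, platform: str, sample_groups: Mapping[str, str]
) -> ExpressionMatrix:
    """Platform-specific normalization of a raw genes x samples matrix.

    TPM values get the 1e-3 offset; FPKM values become ln(FPKM + 1) per
    sample (group averaging happens downstream); microarray log2 RMA values
    pass through unchanged.
    """
    if platform not in PLATFORMS:
        raise ValueError(f"unknown platform {platform!r}")
    if platform != "microarray_log2RMA" and (raw.values < 0).any():
        raise ValueError("negative raw abundance values")
    if platform == "rnaseq_TPM":
        values = raw + 1e-3
    elif platform == "stage_FPKM":
        values = np.log1p(raw)
    else:
        values = raw.copy()
    return ExpressionMatrix(platform, values, dict(sample_groups))


@dataclass
class SexBiasCall:
    gene_id: str
    call: str  # "male" | "female" | "unbiased" | "no_data"
    p_value: float | None
    platform: str


def call_sex_bias(
    m: ExpressionMatrix,
    gene: str,
    male_group: str,
    female_group: str,
    alpha: float = 0.05,
) -> SexBiasCall:
    """Two-tailed Student's t test between male and female organ samples.

    male if p < alpha with higher male mean, female if p < alpha with higher
    female mean, unbiased otherwise; no_data when the gene is absent or a
    group has fewer than two replicates.
    """
    if gene not in m.values.index:
        return SexBiasCall(gene, "no_data", None, m.platform)
    males = m.group_values(gene, male_group)
    females = m.group_values(gene, female_group)
    if len(males) < 2 or len(females) < 2:
        warnings.warn(f"{gene}: fewer than 2 replicates per group; no_data")
        return SexBiasCall(gene, "no_data", None, m.platform)
    if np.isnan(males).any() or np.isnan(females).any():
        return SexBiasCall(gene, "no_data", None, m.platform)
    p = stats.ttest_ind(males, females, equal_var=True).pvalue
    if np.isnan(p):  # identical constant groups
        return SexBiasCall(gene, "unbiased", 1.0, m.platform)
    if p < alpha:
        call = "male" if males.mean() > females.mean() else "female"
    else:
        call = "unbiased"
    return SexBiasCall(gene, call, float(p), m.platform)


def call_sex_bias_all(
    m: ExpressionMatrix,
    male_group: str,
    female_group: str,
    genes: Iterable[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Sex-bias calls for many genes as a DataFrame (gene_id, call, p_value)."""
    genes = list(genes) if genes is not None else list(m.values.index)
    calls = [call_sex_bias(m, g, male_group, female_group, alpha) for g in genes]
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "call": [c.call for c in calls],
            "p_value": [c.p_value for c in calls],
        }
    )


@dataclass
class StageProfile:
    gene_id: str
    stage_means: tuple[float, float, float, float]  # ln(FPKM+1) scale
    profile_class: str = ""

    def __post_init__(self) -> None:
        if not self.profile_class:
            self.profile_class = classify_stage_profile(self.stage_means)


def classify_stage_profile(stage_means: Sequence[float]) -> str:
    """"later_stage_max" iff the best post-premeiotic stage mean strictly
    exceeds the premeiotic mean; ties are premeiotic_max."""
    if len(stage_means) != 4 or any(v is None or np.isnan(v) for v in stage_means):
        return "no_data"
    return (
        "later_stage_max"
        if max(stage_means[1:]) > stage_means[0]
        else "premeiotic_max"
    )


def stage_profile(m: ExpressionMatrix, gene: str) -> StageProfile:
    """Per-stage mean ln(FPKM+1) profile of one gene."""
    if gene not in m.values.index:
        return StageProfile(gene, (np.nan,) * 4, "no_data")
    means = tuple(
        float(np.mean(m.group_values(gene, g))) for g in SPERMATOGENESIS_STAGES
    )
    return StageProfile(gene, means)


def paired_wilcoxon(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two-sided",
) -> float:
    """Paired Wilcoxon signed-rank p value.

    Zero differences are dropped (Wilcoxon convention); the exact null
    distribution is used for n <= 25 without ties, the continuity-corrected
    normal approximation otherwise.  ``alternative`` is "two-sided",
    "greater" (a > b) or "less".
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    alt = {"two_sided": "two-sided", "one_tailed": "greater"}.get(
        alternative, alternative
    )
    d = a - b
    if np.all(d == 0):
        return 1.0
    res = stats.wilcoxon(
        a, b, zero_method="wilcox", correction=True, alternative=alt, method="auto"
    )
    return float(res.pvalue)


@dataclass
class CrossTab:
    """A 2x2 contingency table with the attached association statistics."""

    name: str
    rows: tuple[str, str]
    cols: tuple[str, str]
    table: np.ndarray
    odds_ratio: float
    ci95: tuple[float, float]
    fisher_p: float
    proportions: dict[str, float] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        name: str,
        rows: tuple[str, str],
        cols: tuple[str, str],
        table: np.ndarray,
        proportions: dict[str, float] | None = None,
    ) -> "CrossTab":
        return cls(
            name=name,
            rows=rows,
            cols=cols,
            table=table,
            odds_ratio=odds_ratio(table),
            ci95=woolf_ci(table),
            fisher_p=fisher_exact(table.astype(int)),
            proportions=proportions or {},
        )


def _pct(num: float, den: float) -> float:
    return 100.0 * num / den if den else float("nan")


def crosstab_report(df: pd.DataFrame) -> dict[str, CrossTab]:
    """Contingency tables relating sex bias to age group, movement direction
    and spermatogenesis profile.

    ``df`` holds one row per retrogene with columns ``gene_id`` and ``bias``
    (male/female/unbiased/no_data), optionally ``age_group`` (young/old),
    ``direction`` (X->A/A->A/A->X) and ``profile_class``
    (later_stage_max/premeiotic_max).  Emitted tables (where the columns
    allow): male-vs-female bias by age group, by movement direction among
    young retrogenes, and male-vs-rest bias by stage profile, each with the
    odds ratio, Woolf 95% CI and two-sided Fisher exact p.
    """
    if "bias" not in df.columns or "gene_id" not in df.columns:
        raise ValueError("need gene_id and bias columns")
    biased = df[df["bias"].isin(["male", "female"])]
    report: dict[str, CrossTab] = {}

    if "age_group" in df.columns:
        sub = biased.dropna(subset=["age_group"])
        a = ((sub.age_group == "young") & (sub.bias == "male")).sum()
        b = ((sub.age_group == "young") & (sub.bias == "female")).sum()
        c = ((sub.age_group == "old") & (sub.bias == "male")).sum()
        d = ((sub.age_group == "old") & (sub.bias == "female")).sum()
        report["male_bias_by_age"] = CrossTab.build(
            "male_bias_by_age",
            rows=("young", "old"),
            cols=("male", "female"),
            table=np.array([[a, b], [c, d]]),
            proportions={
                "young_male_pct": _pct(a, a + b),
                "old_male_pct": _pct(c, c + d),
            },
        )

    if {"age_group", "direction"} <= set(df.columns):
        sub = biased[(biased.age_group == "young")]
        a = ((sub.direction == "X->A") & (sub.bias == "male")).sum()
        b = ((sub.direction == "X->A") & (sub.bias == "female")).sum()
        c = ((sub.direction == "A->A") & (sub.bias == "male")).sum()
        d = ((sub.direction == "A->A") & (sub.bias == "female")).sum()
        report["male_bias_by_direction_young"] = CrossTab.build(
            "male_bias_by_direction_young",
            rows=("X->A", "A->A"),
            cols=("male", "female"),
            table=np.array([[a, b], [c, d]]),
            proportions={
                "xa_male_pct": _pct(a, a + b),
                "aa_female_pct": _pct(d, c + d),
            },
        )

    if "profile_class" in df.columns:
        sub = df[
            df["profile_class"].isin(["later_stage_max", "premeiotic_max"])
            & df["bias"].isin(["male", "female", "unbiased"])
        ]
        a = ((sub.profile_class == "later_stage_max") & (sub.bias == "male")).sum()
        b = ((sub.profile_class == "later_stage_max") & (sub.bias != "male")).sum()
        c = ((sub.profile_class == "premeiotic_max") & (sub.bias == "male")).sum()
        d = ((sub.profile_class == "premeiotic_max") & (sub.bias != "male")).sum()
        report["male_bias_by_profile"] = CrossTab.build(
            "male_bias_by_profile",
            rows=("later_stage_max", "premeiotic_max"),
            cols=("male", "not_male"),
            table=np.array([[a, b], [c, d]]),
            proportions={
                "later_stage_pct": _pct(a + b, a + b + c + d),
                "later_male_pct": _pct(a, a + b),
            },
        )

    if not report:
        raise ValueError("no joinable annotation columns in input")
    return report
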