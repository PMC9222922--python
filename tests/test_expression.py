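"""Normalization, sex-bias calls, stage profiles, paired Wilcoxon and the
contingency reports."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from retrotraffic.expression_analysis import (
    ExpressionMatrix,
    call_sex_bias,
    call_sex_bias_all,
    classify_stage_profile,
    crosstab_report,
    normalize,
    paired_wilcoxon,
    stage_profile,
)
from retrotraffic.synthetic_data import analytic_ttest_power


def matrix_from(rows, n=4, groups=("testis", "ovary"), platform="microarray_log2RMA"):
    """rows: gene -> (group1 replicate values, group2 replicate values)."""
    samples = [f"{groups[0]}_{i}" for i in range(n)] + [
        f"{groups[1]}_{i}" for i in range(n)
    ]
    sample_groups = {s: s.rsplit("_", 1)[0] for s in samples}
    data = {g: list(v1) + list(v2) for g, (v1, v2) in rows.items()}
    df = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    return ExpressionMatrix(platform, df, sample_groups)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def test_normalize_fpkm_log1p():
    raw = pd.DataFrame({"s1": [0.0, math.e - 1]}, index=["g1", "g2"])
    m = normalize(raw, "stage_FPKM", {"s1": "premeiotic"})
    assert m.values.loc["g1", "s1"] == pytest.approx(0.0)
    assert m.values.loc["g2", "s1"] == pytest.approx(1.0)


def test_normalize_tpm_offset():
    raw = pd.DataFrame({"s1": [5.0]}, index=["g1"])
    m = normalize(raw, "rnaseq_TPM", {"s1": "male_repro"})
    assert m.values.loc["g1", "s1"] == pytest.approx(5.001)


def test_normalize_rejects_negative_abundance():
    raw = pd.DataFrame({"s1": [-1.0]}, index=["g1"])
    with pytest.raises(ValueError):
        normalize(raw, "rnaseq_TPM", {"s1": "male_repro"})


# ---------------------------------------------------------------------------
# sex-bias calls
# ---------------------------------------------------------------------------


def test_identical_groups_unbiased():
    m = matrix_from({"g1": ([5, 6, 7, 8], [5, 6, 7, 8]), "g2": ([4] * 4, [4] * 4)})
    assert call_sex_bias(m, "g1", "testis", "ovary").call == "unbiased"
    assert call_sex_bias(m, "g2", "testis", "ovary").call == "unbiased"


def test_missing_gene_and_single_replicate_no_data():
    m = matrix_from({"g1": ([5, 6, 7, 8], [5, 6, 7, 8])})
    assert call_sex_bias(m, "absent", "testis", "ovary").call == "no_data"
    m1 = matrix_from({"g1": ([5.0], [6.0])}, n=1)
    with pytest.warns(UserWarning):
        assert call_sex_bias(m1, "g1", "testis", "ovary").call == "no_data"


def test_label_flips_when_groups_swap():
    rng = np.random.default_rng(0)
    rows = {
        f"g{i}": (rng.normal(6 + (i % 3 - 1), 0.4, 4), rng.normal(6, 0.4, 4))
        for i in range(30)
    }
    m = matrix_from(rows)
    flip = {"male": "female", "female": "male", "unbiased": "unbiased"}
    for g in rows:
        fwd = call_sex_bias(m, g, "testis", "ovary")
        rev = call_sex_bias(m, g, "ovary", "testis")
        assert rev.call == flip[fwd.call]
        assert rev.p_value == pytest.approx(fwd.p_value)


def test_type_one_error_near_alpha():
    """Null simulation: fraction of biased calls within binomial 99% bounds
    of alpha = 0.05 (2000 genes, 4 replicates/group)."""
    rng = np.random.default_rng(1)
    n_genes = 2000
    rows = {
        f"g{i}": (rng.normal(6, 0.5, 4), rng.normal(6, 0.5, 4))
        for i in range(n_genes)
    }
    calls = call_sex_bias_all(matrix_from(rows), "testis", "ovary")
    rate = (calls["call"] != "unbiased").mean()
    sd = math.sqrt(0.05 * 0.95 / n_genes)
    assert abs(rate - 0.05) < 2.576 * sd


def test_power_matches_closed_form():
    """2-fold male effect: empirical detection rate within binomial 99%
    bounds of the analytic noncentral-t power."""
    rng = np.random.default_rng(2)
    delta, sigma, n, n_genes = 1.0, 0.5, 4, 1500
    rows = {
        f"g{i}": (rng.normal(6 + delta / 2, sigma, n), rng.normal(6 - delta / 2, sigma, n))
        for i in range(n_genes)
    }
    calls = call_sex_bias_all(matrix_from(rows, n=n), "testis", "ovary")
    power = analytic_ttest_power(delta, sigma, n)
    rate = (calls["call"] == "male").mean()
    sd = math.sqrt(power * (1 - power) / n_genes)
    assert abs(rate - power) < 2.576 * sd


# ---------------------------------------------------------------------------
# stage profiles
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "means,expected",
    [
        ((3, 1, 1, 1), "premeiotic_max"),
        ((1, 1, 1, 2), "later_stage_max"),
        ((2, 2, 2, 2), "premeiotic_max"),  # strict inequality: tie stays premeiotic
    ],
)
def test_classify_stage_profile(means, expected):
    assert classify_stage_profile(means) == expected


def test_profile_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    for _ in range(50):
        means = tuple(rng.uniform(0, 3, 4))
        base = classify_stage_profile(means)
        assert classify_stage_profile(tuple(np.exp(means))) == base
        assert classify_stage_profile(tuple(2 * m + 1 for m in means)) == base


def test_stage_profile_from_matrix(expression):
    matrices, ledger = expression
    stage_m = matrices["stage"]
    profiles = {
        g: stage_profile(stage_m, g).profile_class
        for g in ledger.profile_truth
    }
    truth = ledger.profile_truth
    agreement = np.mean([profiles[g] == truth[g] for g in truth])
    assert agreement >= 0.9  # sigma = 0.3 noise on well-separated trajectories


# ---------------------------------------------------------------------------
# paired Wilcoxon
# ---------------------------------------------------------------------------


def _wilcoxon_oracle(a, b, alternative):
    """Exact p by enumerating all 2^n sign assignments (distinct nonzero |d|)."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([0, 1], repeat=n)
    ]
    total = 2 ** n
    p_ge = sum(w >= w_obs for w in ws) / total
    p_le = sum(w <= w_obs for w in ws) / total
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


def test_wilcoxon_equal_vectors_p_one():
    assert paired_wilcoxon([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == 1.0


def test_wilcoxon_constant_shift_one_tailed():
    b = np.arange(10, dtype=float)
    assert paired_wilcoxon(b + 1, b, "greater") == pytest.approx(1 / 1024)


def test_wilcoxon_matches_enumeration_oracle():
    rng = np.random.default_rng(4)
    for _ in range(15):
        n = int(rng.integers(6, 11))
        a = rng.normal(0, 1, n)
        b = a + rng.normal(0.3, 1, n)
        for alt in ("two-sided", "greater", "less"):
            assert paired_wilcoxon(a, b, alt) == pytest.approx(
                _wilcoxon_oracle(a, b, alt)
            ), (n, alt)


def test_wilcoxon_rejects_tiny_samples():
    with pytest.raises(ValueError):
        paired_wilcoxon([1, 2], [2, 3])


# ---------------------------------------------------------------------------
# contingency reports
# ---------------------------------------------------------------------------


def study_calls_frame():
    """Per-gene table reproducing the printed young/old, direction and
    profile counts."""
    rows = []
    mk = lambda n, **kw: [dict(kw, gene_id=f"g{len(rows)+i}") for i in range(n)]
    # young sex-biased: X->A 10 male + 2 female; A->A 1 male + 4 female
    rows += mk(10, bias="male", age_group="young", direction="X->A")
    rows += mk(2, bias="female", age_group="young", direction="X->A")
    rows += mk(1, bias="male", age_group="young", direction="A->A")
    rows += mk(4, bias="female", age_group="young", direction="A->A")
    # old sex-biased: 1 male + 6 female
    rows += mk(1, bias="male", age_group="old", direction="A->A")
    rows += mk(6, bias="female", age_group="old", direction="A->A")
    # X->A young profiles: 12 later-stage (10 male), 7 premeiotic (1 male)
    rows += mk(10, bias="male", profile_class="later_stage_max")
    rows += mk(2, bias="female", profile_class="later_stage_max")
    rows += mk(1, bias="male", profile_class="premeiotic_max")
    rows += mk(5, bias="female", profile_class="premeiotic_max")
    rows += mk(1, bias="unbiased", profile_class="premeiotic_max")
    df = pd.DataFrame(rows)
    df["gene_id"] = [f"g{i}" for i in range(len(df))]
    return df


def test_crosstab_study_tables():
    report = crosstab_report(study_calls_frame())
    age = report["male_bias_by_age"]
    assert age.table.tolist() == [[11, 6], [1, 6]]
    assert age.odds_ratio == pytest.approx(11.0)
    assert age.proportions["young_male_pct"] == pytest.approx(64.71, abs=0.01)
    assert age.proportions["old_male_pct"] == pytest.approx(14.29, abs=0.01)

    direction = report["male_bias_by_direction_young"]
    assert direction.proportions["xa_male_pct"] == pytest.approx(83.33, abs=0.01)
    assert direction.proportions["aa_female_pct"] == pytest.approx(80.0, abs=0.01)

    profile = report["male_bias_by_profile"]
    assert profile.table.tolist() == [[10, 2], [1, 6]]
    assert profile.odds_ratio == pytest.approx(30.0)
    assert profile.fisher_p < 0.05
    assert profile.proportions["later_stage_pct"] == pytest.approx(63.16, abs=0.01)


def test_crosstab_matches_ledger_bookkeeping(world):
    """Tables built from ground-truth labels equal direct recounts of the
    generator's ledger."""
    _, _, ledger = world
    rows = []
    for e in ledger.real_events():
        rows.append({
            "gene_id": e.retro_id,
            "bias": ledger.bias_truth[e.retro_id],
            "age_group": "young" if int(e.stage[2:]) <= 7 else "old",
            "direction": e.direction,
            "profile_class": ledger.profile_truth.get(e.retro_id),
        })
    df = pd.DataFrame(rows)
    report = crosstab_report(df)
    young_male = sum(
        1 for r in rows if r["age_group"] == "young" and r["bias"] == "male"
    )
    assert report["male_bias_by_age"].table[0, 0] == young_male


def test_crosstab_requires_joinable_columns():
    with pytest.raises(ValueError):
        crosstab_report(pd.DataFrame({"gene_id": ["g1"], "bias": ["male"]}))
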