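"""Exact and rank tests of the association battery against enumeration oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from telostrat import (
    StratifiedCohort,
    bh_fdr,
    compare_features,
    fisher_exact_2x2,
    spearman_corr,
    welch_t,
    wilcoxon_rank_sum,
)

from oracles import (
    fisher_oracle,
    hodges_lehmann_oracle,
    spearman_oracle,
    welch_oracle,
    wilcoxon_exact_oracle,
)


# ---------------------------------------------------------------- fisher


def test_fisher_independence_table():
    p, or_ = fisher_exact_2x2([[5, 5], [5, 5]])
    assert p == pytest.approx(1.0)
    assert or_ == pytest.approx(1.0)


def test_fisher_extreme_table_exact_value():
    """Only the two extreme tables qualify: p = 2 / C(20, 10)."""
    p, or_ = fisher_exact_2x2([[10, 0], [0, 10]])
    assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)
    # Haldane-corrected cross-product ratio
    assert or_ == pytest.approx((10.5 * 10.5) / (0.5 * 0.5))


def test_fisher_matches_enumeration_oracle(rng):
    tables = [[[3, 1], [1, 3]]]
    for _ in range(30):
        t = rng.integers(0, 11, size=(2, 2))
        if t.sum() < 1 or t.sum() > 40:
            continue
        tables.append(t.tolist())
    for t in tables:
        if (np.array(t).sum(axis=0) == 0).any() or (np.array(t).sum(axis=1) == 0).any():
            continue
        p, _ = fisher_exact_2x2(t)
        assert p == pytest.approx(fisher_oracle(t), abs=1e-12)


def test_fisher_zero_margin():
    p, or_ = fisher_exact_2x2([[0, 0], [3, 4]])
    assert p == 1.0 and math.isnan(or_)


def test_fisher_symmetry(rng):
    t = [[7, 2], [3, 9]]
    p1, or1 = fisher_exact_2x2(t)
    p2, or2 = fisher_exact_2x2([t[1], t[0]])  # swap group rows
    assert p1 == pytest.approx(p2, rel=1e-12)
    assert or2 == pytest.approx(1.0 / or1, rel=1e-12)


# ---------------------------------------------------------------- welch


def test_welch_identical_groups():
    t, p, d = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert (t, p, d) == (0.0, 1.0, 0.0)


def test_welch_unit_shift_unit_pooled_sd():
    _, _, d = welch_t([2, 3, 4], [1, 2, 3])
    assert d == pytest.approx(1.0)


def test_welch_matches_textbook_oracle(rng):
    x = rng.normal(0.3, 1.2, 30)
    y = rng.normal(0.0, 0.8, 30)
    t, p, _ = welch_t(x, y)
    t_o, _, p_o = welch_oracle(x, y)
    assert t == pytest.approx(t_o, abs=1e-10)
    assert p == pytest.approx(p_o, abs=1e-10)


def test_welch_sign_symmetry(rng):
    x, y = rng.normal(1, 1, 20), rng.normal(0, 1, 25)
    t1, p1, d1 = welch_t(x, y)
    t2, p2, d2 = welch_t(y, x)
    assert d2 == pytest.approx(-d1) and p2 == pytest.approx(p1)


def test_welch_insufficient_n():
    with pytest.raises(ValueError):
        welch_t([1.0], [1.0, 2.0])


# ---------------------------------------------------------------- wilcoxon


def test_wilcoxon_disjoint_toy_exact():
    w, p, hl = wilcoxon_rank_sum([4, 5, 6], [1, 2, 3])
    assert p == pytest.approx(0.1, abs=1e-12)
    assert hl == pytest.approx(3.0)
    assert w == 4 + 5 + 6  # rank sum of the larger group


def test_wilcoxon_identical_groups_zero_shift():
    _, _, hl = wilcoxon_rank_sum([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
    assert hl == 0.0


def test_wilcoxon_exact_matches_enumeration(rng):
    for _ in range(10):
        nx, ny = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        vals = rng.permutation(np.arange(1, 21, dtype=float))[: nx + ny]
        x, y = vals[:nx], vals[nx:]
        _, p, hl = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(wilcoxon_exact_oracle(x, y), abs=1e-12)
        assert hl == pytest.approx(hodges_lehmann_oracle(x, y))


def test_wilcoxon_hl_symmetry(rng):
    x, y = rng.normal(1, 1, 15), rng.normal(0, 1, 12)
    _, p1, hl1 = wilcoxon_rank_sum(x, y)
    _, p2, hl2 = wilcoxon_rank_sum(y, x)
    assert hl2 == pytest.approx(-hl1)
    assert p2 == pytest.approx(p1, rel=1e-9)


def test_wilcoxon_empty_group():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------- spearman


def test_spearman_monotone_extremes():
    u = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
    assert spearman_corr(u, np.exp(u))[0] == pytest.approx(1.0)
    assert spearman_corr(u, -(u**3))[0] == pytest.approx(-1.0)


def test_spearman_ties_match_rank_construction_oracle(rng):
    u = rng.integers(0, 5, 40).astype(float)  # heavy ties
    v = u + rng.integers(0, 3, 40)
    rho, _ = spearman_corr(u, v)
    assert rho == pytest.approx(spearman_oracle(u, v), abs=1e-12)


def test_spearman_constant_vector_flagged():
    rho, p = spearman_corr([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
    assert math.isnan(rho) and math.isnan(p)


# ---------------------------------------------------------------- BH FDR


def test_bh_stepup_by_hand():
    assert bh_fdr([0.01, 0.02, 0.03]).tolist() == pytest.approx([0.03, 0.03, 0.03])


def test_bh_degenerate_cases():
    assert bh_fdr([0.2, 0.2, 0.2]).tolist() == pytest.approx([0.2, 0.2, 0.2])
    assert bh_fdr([0.07]).tolist() == [0.07]
    assert bh_fdr([]).size == 0
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


def test_bh_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    p = rng.random(50)
    q = bh_fdr(p)
    q_sm = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(q, q_sm, atol=1e-12)


def test_bh_monotone_in_p(rng):
    p = rng.random(30)
    q = bh_fdr(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-15).all()  # monotone non-decreasing in p
    m = len(p)
    ranks = np.empty(m)
    ranks[order] = np.arange(1, m + 1)
    # step-up q is bounded above by the raw BH ratio and below by p itself
    assert (q <= p * m / ranks + 1e-12).all()
    assert (q >= p - 1e-12).all()


# ---------------------------------------------------------------- battery


def _toy_cohort(n_low=30, n_high=30):
    ids = [f"s{i}" for i in range(n_low + n_high)]
    group = np.array(["low"] * n_low + ["high"] * n_high)
    return StratifiedCohort(
        sample_ids=ids,
        group=group,
        consensus_fraction=np.ones(n_low + n_high),
        boundary=0.0,
        n_runs=1,
        centroids=(-1.0, 1.0),
    )


def test_compare_features_constant_feature_is_null():
    cohort = _toy_cohort(5, 5)
    feats = pd.DataFrame({"flat": np.ones(10)}, index=cohort.sample_ids)
    out = compare_features(feats, cohort, {"flat": "welch_t"})
    row = out.iloc[0]
    assert row.p == 1.0 and row.q == 1.0 and row.direction == "none"


def test_compare_features_planted_shift_directions(rng):
    cohort = _toy_cohort(40, 40)
    feats = pd.DataFrame(
        {
            "up_in_high": np.r_[rng.normal(0, 1, 40), rng.normal(2, 1, 40)],
            "up_in_low": np.r_[rng.normal(2, 1, 40), rng.normal(0, 1, 40)],
            "flag": np.r_[np.ones(30), np.zeros(10), np.zeros(35), np.ones(5)],
        },
        index=cohort.sample_ids,
    )
    out = compare_features(
        feats, cohort,
        {"up_in_high": "welch_t", "up_in_low": "wilcoxon", "flag": "fisher"},
    ).set_index("feature_id")
    assert out.loc["up_in_high", "direction"] == "high_enriched"
    assert out.loc["up_in_high", "q"] < 0.05
    assert out.loc["up_in_low", "direction"] == "low_enriched"
    assert out.loc["flag", "direction"] == "low_enriched"
    assert out.loc["flag", "effect"] > 1


def test_compare_features_unknown_test_and_missing():
    cohort = _toy_cohort(5, 5)
    feats = pd.DataFrame(
        {"x": np.arange(10.0), "gone": [np.nan] * 10}, index=cohort.sample_ids
    )
    with pytest.raises(ValueError):
        compare_features(feats, cohort, {"x": "anova"})
    out = compare_features(feats, cohort, {"x": "welch_t", "gone": "welch_t"})
    assert out["feature_id"].tolist() == ["x"]  # all-missing feature skipped
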