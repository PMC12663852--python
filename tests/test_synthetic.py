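"""Synthetic cohort generator: composition, determinism, planted effects."""

import numpy as np
import pandas as pd
import pytest

from telostrat import (
    SyntheticCohortConfig,
    simulate_activity_scores,
    simulate_clinical,
    simulate_cohort,
    simulate_expression,
    simulate_genomic_features,
    simulate_single_cells,
    welch_t,
    wilcoxon_rank_sum,
)

from oracles import hodges_lehmann_oracle


def _cfg(**kw):
    defaults = dict(n_genes=300, signature_size=30, coupling_rho=0.0, n_cells=200)
    defaults.update(kw)
    return SyntheticCohortConfig(**defaults)


# ----------------------------------------------------------- validation


def test_config_invariants_enforced():
    with pytest.raises(ValueError):
        SyntheticCohortConfig(n_samples=3)
    with pytest.raises(ValueError):
        SyntheticCohortConfig(mu_low=2.0, mu_high=1.0)
    with pytest.raises(ValueError):
        SyntheticCohortConfig(signature_size=10_000, n_genes=100)
    with pytest.raises(ValueError):
        SyntheticCohortConfig(clinical_or={"x": -1.0})
    with pytest.raises(ValueError):
        SyntheticCohortConfig(mix_high=1.0)
    with pytest.raises(ValueError):
        SyntheticCohortConfig(senescence_d=0.5, coupling_rho=0.5)


# ----------------------------------------------------------- scores


def test_score_composition_is_exact():
    scores, labels = simulate_activity_scores(_cfg(n_samples=100, mix_high=0.3, seed=7))
    assert (labels == "high").sum() == 30
    assert (labels == "low").sum() == 70
    assert list(scores.index) == list(labels.index)


def test_score_determinism_bit_identical():
    cfg = _cfg(n_samples=100, mix_high=0.3, seed=7)
    s1, l1 = simulate_activity_scores(cfg)
    s2, l2 = simulate_activity_scores(cfg)
    assert (s1 == s2).all() and (l1 == l2).all()


def test_score_group_means_recovered():
    cfg = _cfg(n_samples=2000, mu_low=0.0, mu_high=3.0, sigma=1.0, seed=1)
    scores, labels = simulate_activity_scores(cfg)
    high_mean = scores[labels == "high"].mean()
    assert abs(high_mean - 3.0) < 0.1  # 3 sigma / sqrt(n_high) tolerance


# ----------------------------------------------------------- expression


def test_expression_null_effect_is_calibrated():
    """With no planted effect, signature-gene t-tests behave as null tests."""
    cfg = _cfg(n_samples=100, n_genes=200, signature_size=200, senescence_d=0.0, seed=5)
    # make every gene a "signature" gene so we test 200 null genes at once
    scores, labels = simulate_activity_scores(cfg)
    expr = simulate_expression(cfg, labels)
    lab = labels.to_numpy()
    pvals = [
        welch_t(expr.loc[g, lab == "low"], expr.loc[g, lab == "high"])[1]
        for g in expr.index
    ]
    frac = np.mean(np.array(pvals) < 0.05)
    assert frac < 0.12  # ~0.05 expected, binomial slack over 200 genes


def test_expression_planted_shift_direction():
    cfg = _cfg(n_samples=400, senescence_d=1.2, seed=3)
    scores, labels = simulate_activity_scores(cfg)
    expr = simulate_expression(cfg, labels)
    cohort = simulate_cohort(cfg, include_cells=False)
    lab = labels.to_numpy()
    sig = cohort.signature_genes.genes
    higher_in_low = [
        expr.loc[g, lab == "low"].mean() > expr.loc[g, lab == "high"].mean()
        for g in sig
    ]
    assert np.mean(higher_in_low) >= 0.95
    assert (expr.to_numpy() >= 0).all()


def test_expression_determinism():
    cfg = _cfg(n_samples=60, seed=11)
    _, labels = simulate_activity_scores(cfg)
    e1 = simulate_expression(cfg, labels)
    e2 = simulate_expression(cfg, labels)
    assert e1.equals(e2)


# ----------------------------------------------------------- clinical


def _sample_or(clinical, labels, cov):
    is_low = labels == "low"
    a = ((clinical[cov] == 1) & is_low).sum()
    b = ((clinical[cov] == 0) & is_low).sum()
    c = ((clinical[cov] == 1) & ~is_low).sum()
    d = ((clinical[cov] == 0) & ~is_low).sum()
    return (a * d) / (b * c)


def test_clinical_null_odds_ratio_unbiased():
    ors = []
    for seed in range(50):
        cfg = _cfg(n_samples=500, clinical_or={"sex_female": 1.0}, seed=seed)
        _, labels = simulate_activity_scores(cfg)
        clin = simulate_clinical(cfg, labels)
        ors.append(_sample_or(clin, labels, "sex_female"))
    assert abs(np.mean(ors) - 1.0) < 0.15


def test_clinical_planted_odds_ratio():
    cfg = _cfg(n_samples=5000, clinical_or={"sex_female": 2.0}, seed=11)
    _, labels = simulate_activity_scores(cfg)
    clin = simulate_clinical(cfg, labels)
    assert 1.6 <= _sample_or(clin, labels, "sex_female") <= 2.5
    assert clin["age"].between(18, 90).all()
    assert set(clin["sex"]) <= {"female", "male"}


def test_clinical_determinism():
    cfg = _cfg(n_samples=80, seed=2)
    _, labels = simulate_activity_scores(cfg)
    assert simulate_clinical(cfg, labels).equals(simulate_clinical(cfg, labels))


# ----------------------------------------------------------- genomic


def test_genomic_null_wilcoxon_calibrated():
    """Equal TMB means: the rank-sum test should essentially never scream."""
    calm = 0
    n_seeds = 100
    for seed in range(n_seeds):
        cfg = _cfg(n_samples=500, tmb_mean_low=5.0, tmb_mean_high=5.0, seed=seed)
        _, labels = simulate_activity_scores(cfg)
        gen = simulate_genomic_features(cfg, labels)
        lab = labels.to_numpy()
        _, p, _ = wilcoxon_rank_sum(gen.loc[lab == "high", "tmb"], gen.loc[lab == "low", "tmb"])
        calm += p > 0.001
    assert calm / n_seeds >= 0.95


def test_genomic_planted_tmb_shift_positive_hl():
    cfg = _cfg(n_samples=500, tmb_mean_low=5.0, tmb_mean_high=15.0, seed=2)
    _, labels = simulate_activity_scores(cfg)
    gen = simulate_genomic_features(cfg, labels)
    lab = labels.to_numpy()
    hi = gen.loc[lab == "high", "tmb"].to_numpy()
    lo = gen.loc[lab == "low", "tmb"].to_numpy()
    _, _, hl = wilcoxon_rank_sum(hi, lo)
    assert hl > 0
    assert hl == pytest.approx(hodges_lehmann_oracle(hi, lo))
    assert gen["cna_fraction"].between(0, 1).all()
    assert gen["loh_fraction"].between(0, 1).all()
    assert (gen["tl_ratio"] > 0).all()


def test_genomic_determinism():
    cfg = _cfg(n_samples=60, seed=9)
    _, labels = simulate_activity_scores(cfg)
    assert simulate_genomic_features(cfg, labels).equals(
        simulate_genomic_features(cfg, labels)
    )


# ----------------------------------------------------------- single cells


def test_cells_composition_exact():
    sc = simulate_single_cells(_cfg(n_cells=1000, frac_cycling=0.4, seed=4))
    assert sc.cycling.sum() == 400


def test_cells_signature_depressed_in_cycling():
    cfg = _cfg(n_cells=600, senescence_d=0.8, seed=6)
    sc = simulate_single_cells(cfg)
    cohort = simulate_cohort(cfg, include_cells=True)
    sig_idx = [sc.gene_ids.index(g) for g in cohort.signature_genes.genes]
    counts = sc.dense()
    mean_noncyc = counts[np.ix_(sig_idx, ~sc.cycling)].mean()
    mean_cyc = counts[np.ix_(sig_idx, sc.cycling)].mean()
    assert mean_noncyc > mean_cyc


def test_cells_errors_and_determinism():
    with pytest.raises(ValueError):
        simulate_single_cells(_cfg(n_cells=5))
    cfg = _cfg(n_cells=100, seed=8)
    a, b = simulate_single_cells(cfg), simulate_single_cells(cfg)
    assert (a.dense() == b.dense()).all()
    assert (a.cycling == b.cycling).all()


# ----------------------------------------------------------- bundle


def test_cohort_tables_share_sample_index():
    cohort = simulate_cohort(_cfg(n_samples=50, seed=12), include_cells=False)
    idx = list(cohort.scores.index)
    assert list(cohort.true_labels.index) == idx
    assert list(cohort.expression.columns) == idx
    assert list(cohort.clinical.index) == idx
    assert list(cohort.genomic.index) == idx
    n_high = (cohort.true_labels == "high").sum()
    assert n_high == round(cohort.config.mix_high * cohort.config.n_samples)


def test_cohort_roundtrip_via_text_formats(tmp_path):
    from telostrat import io as tio
    from telostrat.synthetic import write_cohort

    cohort = simulate_cohort(_cfg(n_samples=30, n_cells=50, seed=13), include_cells=True)
    write_cohort(cohort, tmp_path)
    scores = tio.read_scores_tsv(tmp_path / "activity_scores.tsv")
    assert np.allclose(scores.to_numpy(), cohort.scores.to_numpy(), rtol=1e-9)
    expr = tio.read_expression_tsv(tmp_path / "expression.tsv")
    assert expr.shape == cohort.expression.shape
    sets = tio.read_gmt(tmp_path / "gene_sets.gmt")
    assert sets[0].genes == cohort.signature_genes.genes
    cells = tio.read_mtx_dir(tmp_path / "cells")
    assert (cells.dense() == cohort.cells.dense()).all()
    assert (cells.cycling == cohort.cells.cycling).all()
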