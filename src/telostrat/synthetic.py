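"""Synthetic tumour-cohort generator with planted statistical structure.

The generator emulates the statistical skeleton that the stratification
and association analyses assume in real pan-cancer data:

* a two-component Gaussian mixture of per-sample telomerase-activity
  scores (the default 43 % high / 57 % low split mirrors the typical
  pan-cancer proportion);
* a senescence gene programme whose signature genes are shifted upward
  in low-activity samples by a configurable standardised effect, with a
  shared continuous latent term calibrated so that the Spearman
  correlation between activity scores and the single-sample senescence
  score hits a target (default -0.57);
* genomic-instability covariates (tumour mutation burden, copy-number-
  altered fraction, loss-of-heterozygosity fraction, tumour-to-normal
  telomere-length ratio) with group-dependent locations;
* binary clinical covariates with configurable odds ratios for
  membership in the low-activity group, plus ages and stage strings;
* a sparse single-cell count matrix with cycling/non-cycling cells in
  which cycling cells over-express an activity programme and
  under-express the senescence signature.

Group sizes are deterministic (``round(mix_high * n)``) so composition
assertions are exact, and all randomness flows from a single root seed
through a fixed spawning order (one child stream per generator), so any
generator can be re-run in isolation and reproduce its slice of a full
cohort bit for bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .sigscore import GeneSet, SingleCellMatrix, ssgsea_score

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticCohortConfig",
    "SyntheticCohort",
    "simulate_activity_scores",
    "simulate_expression",
    "simulate_clinical",
    "simulate_genomic_features",
    "simulate_single_cells",
    "simulate_cohort",
    "write_cohort",
]

# fixed child-stream order off the root seed; changing it changes every draw
_STREAMS = {
    "scores": 0,
    "expression": 1,
    "clinical": 2,
    "genomic": 3,
    "cells": 4,
    "genes": 5,
}

# stage-string dialects sampled for the clinical table
_STAGE_DIALECTS = [
    "Stage I", "Stage IA", "Stage IB", "Stage II", "Stage IIA", "Stage IIB",
    "stage iii", "Stage IIIB", "Stage IIIC", "Stage IV", "Stage IVA", "NX",
]


@dataclass
class SyntheticCohortConfig:
    """Parameters of the planted cohort.

    Defaults encode the study conditions the downstream analyses expect:
    a 57/43 low/high split, a planted standardised senescence effect of
    0.6 on signature genes (low minus high), an activity-senescence
    Spearman target of -0.57, a modest TMB elevation in the high group
    (negative-binomial means 2.0 vs 3.2 mutations per unit), copy-number
    and LOH fractions elevated in the high group, longer telomeres
    (tumour/normal ratio > 1) in the low group, and a female-sex odds
    ratio of 2 for the low group.
    """

    n_samples: int = 400
    mix_high: float = 0.43
    mu_low: float = 0.0
    mu_high: float = 3.0
    sigma: float = 1.0
    n_genes: int = 2000
    signature_size: int = 125
    senescence_d: float = 0.6
    coupling_rho: float = -0.57
    tmb_mean_low: float = 2.0
    tmb_mean_high: float = 3.2
    tmb_dispersion: float = 3.0
    cna_mean_low: float = 0.25
    cna_mean_high: float = 0.315
    cna_concentration: float = 20.0
    loh_mean_low: float = 0.15
    loh_mean_high: float = 0.25
    tl_median_low: float = 1.1
    tl_median_high: float = 0.9
    tl_sigma: float = 0.3
    clinical_or: Mapping[str, float] = field(
        default_factory=lambda: {"sex_female": 2.0}
    )
    n_cells: int = 1000
    frac_cycling: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be at least 4 for stratification")
        if not (0.0 < self.mix_high < 1.0):
            raise ValueError("mix_high must lie strictly between 0 and 1")
        if self.mu_high <= self.mu_low:
            raise ValueError("mu_high must exceed mu_low")
        if self.sigma <= 0 or self.tmb_dispersion <= 0 or self.tl_sigma <= 0:
            raise ValueError("scale parameters must be positive")
        if self.n_genes < 1 or self.signature_size < 1:
            raise ValueError("gene counts must be positive")
        if self.signature_size > self.n_genes:
            raise ValueError("signature_size cannot exceed n_genes")
        if not (-1.0 <= self.coupling_rho <= 1.0):
            raise ValueError("coupling_rho must lie in [-1, 1]")
        if self.senescence_d > 0 and self.coupling_rho > 0:
            raise ValueError(
                "a positive senescence effect in the low group implies a "
                "non-positive activity-senescence correlation"
            )
        for name in ("tmb_mean_low", "tmb_mean_high"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("cna_mean_low", "cna_mean_high", "loh_mean_low", "loh_mean_high"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie strictly between 0 and 1")
        if self.tl_median_low <= 0 or self.tl_median_high <= 0:
            raise ValueError("telomere-length ratio medians must be positive")
        for cov, or_ in dict(self.clinical_or).items():
            if or_ <= 0:
                raise ValueError(f"odds ratio for {cov!r} must be positive")
        if not (0.0 < self.frac_cycling < 1.0):
            raise ValueError("frac_cycling must lie strictly between 0 and 1")

    @classmethod
    def null(cls, **overrides) -> "SyntheticCohortConfig":
        """A configuration with every planted effect removed.

        The activity mixture itself is retained (groups must still be
        separable) but senescence, genomic, and clinical couplings are
        all null, so any downstream discovery is a false positive.
        """
        params = dict(
            senescence_d=0.0,
            coupling_rho=0.0,
            tmb_mean_high=2.0,
            tmb_mean_low=2.0,
            cna_mean_low=0.25,
            cna_mean_high=0.25,
            loh_mean_low=0.2,
            loh_mean_high=0.2,
            tl_median_low=1.0,
            tl_median_high=1.0,
            clinical_or={"sex_female": 1.0, "smoker": 1.0},
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class SyntheticCohort:
    """Bundle of all generated tables, indexed by the same sample ids."""

    scores: pd.Series
    true_labels: pd.Series
    expression: pd.DataFrame
    signature_genes: GeneSet
    activity_genes: GeneSet
    clinical: pd.DataFrame
    genomic: pd.DataFrame
    cells: Optional[SingleCellMatrix]
    latent_weight: float
    config: SyntheticCohortConfig


def _rng(config: SyntheticCohortConfig, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[stream]])


def _sample_ids(n: int) -> pd.Index:
    return pd.Index([f"S{i + 1:05d}" for i in range(n)], name="sample_id")


def _gene_ids(n: int) -> list[str]:
    return [f"g{i + 1:05d}" for i in range(n)]


def _planted_gene_sets(config: SyntheticCohortConfig) -> tuple[GeneSet, GeneSet]:
    """Signature and activity-programme gene sets, from a dedicated stream.

    Both the bulk and the single-cell generator use these, so the planted
    sets agree across modalities for a given configuration.
    """
    rng = _rng(config, "genes")
    genes = _gene_ids(config.n_genes)
    k = config.signature_size
    n_act = min(k, config.n_genes - k) or 1
    picked = rng.choice(config.n_genes, size=min(k + n_act, config.n_genes), replace=False)
    sig = GeneSet("senescence_signature", tuple(genes[i] for i in sorted(picked[:k])))
    act_idx = sorted(picked[k:]) or [int(picked[0])]
    act = GeneSet("activity_program", tuple(genes[i] for i in act_idx))
    return sig, act


def simulate_activity_scores(
    config: SyntheticCohortConfig,
) -> tuple[pd.Series, pd.Series]:
    """Two-component Gaussian mixture of activity scores with known labels.

    Exactly ``round(mix_high * n)`` samples are labelled ``high`` and
    drawn from Normal(mu_high, sigma); the rest are ``low`` from
    Normal(mu_low, sigma).  Label positions are permuted, so sample order
    carries no information.
    """
    n = config.n_samples
    n_high = int(round(config.mix_high * n))
    if n_high == 0 or n_high == n:
        raise ValueError("mix_high leaves one group empty at this n_samples")
    rng = _rng(config, "scores")
    labels = np.array(["high"] * n_high + ["low"] * (n - n_high))
    rng.shuffle(labels)
    mu = np.where(labels == "high", config.mu_high, config.mu_low)
    values = mu + config.sigma * rng.standard_normal(n)
    ids = _sample_ids(n)
    return (
        pd.Series(values, index=ids, name="activity_score"),
        pd.Series(labels, index=ids, name="true_label"),
    )


def _build_signature_block(
    base: np.ndarray,
    sd: np.ndarray,
    noise: np.ndarray,
    is_low: np.ndarray,
    eta: np.ndarray,
    d: float,
    w: float,
) -> np.ndarray:
    """Signature-gene values for a given latent weight ``w``.

    The shared sample-level programme is ``shift * 1[low] + w * eta``
    with ``shift = d * sqrt(1 + w^2)``, so the realised per-gene
    standardised group difference equals the planted ``d`` regardless of
    ``w`` (the latent term inflates the within-group SD by
    ``sqrt(1 + w^2)``).
    """
    shift = d * math.sqrt(1.0 + w * w)
    program = shift * is_low.astype(float) + w * eta
    return np.maximum(base[:, None] + sd[:, None] * (program[None, :] + noise), 0.0)


def _calibrate_latent_weight(
    config: SyntheticCohortConfig,
    scores: np.ndarray,
    expr: np.ndarray,
    sig_idx: np.ndarray,
    base: np.ndarray,
    sd: np.ndarray,
    sig_noise: np.ndarray,
    is_low: np.ndarray,
    eta: np.ndarray,
    gene_ids: list[str],
    signature: GeneSet,
) -> float:
    """1-D search for the latent weight hitting the Spearman target.

    The objective is the realised Spearman correlation between the
    activity scores and the single-sample senescence score computed on
    the candidate matrix -- the exact quantity the coupling target
    constrains -- evaluated on frozen random draws so the objective is a
    deterministic, effectively monotone function of the weight.
    """
    target = config.coupling_rho

    def rho_at(w: float) -> float:
        mat = expr.copy()
        mat[sig_idx] = _build_signature_block(
            base, sd, sig_noise, is_low, eta, config.senescence_d, w
        )
        frame = pd.DataFrame(mat, index=gene_ids)
        sen = ssgsea_score(frame, signature).scores
        from scipy.stats import spearmanr

        return float(spearmanr(scores, sen).statistic)

    w_max = 4.0
    f0 = rho_at(0.0) - target
    if f0 >= 0.0:
        # even with no dilution the coupling is weaker than the target
        logger.warning(
            "coupling target %.2f unreachable (undiluted rho %.2f); using w=0",
            target, f0 + target,
        )
        return 0.0
    f_hi = rho_at(w_max) - target
    if f_hi <= 0.0:
        logger.warning("coupling target %.2f unreachable within w<=%.1f", target, w_max)
        return w_max
    return float(brentq(lambda w: rho_at(w) - target, 0.0, w_max, xtol=0.02))


def simulate_expression(
    config: SyntheticCohortConfig,
    true_labels: pd.Series,
) -> pd.DataFrame:
    """Non-negative gene-by-sample matrix with a planted senescence programme.

    Background genes are i.i.d. Normal(base_g, sd_g) across samples
    (clipped at zero; bases are large relative to the per-gene SD so
    clipping is rare).  Signature genes carry the group shift plus the
    calibrated shared latent term described in the module docstring.
    """
    return _simulate_expression_impl(config, true_labels)[0]


def _simulate_expression_impl(
    config: SyntheticCohortConfig,
    true_labels: pd.Series,
) -> tuple[pd.DataFrame, float]:
    n = config.n_samples
    if len(true_labels) != n:
        raise ValueError("true_labels length does not match n_samples")
    rng = _rng(config, "expression")
    gene_ids = _gene_ids(config.n_genes)
    signature, _ = _planted_gene_sets(config)
    sig_mask = np.isin(np.asarray(gene_ids, dtype=object), np.asarray(signature.genes, dtype=object))
    sig_idx = np.flatnonzero(sig_mask)

    base = rng.uniform(6.0, 14.0, size=config.n_genes)
    sd = rng.uniform(0.5, 2.0, size=config.n_genes)
    values = np.maximum(
        base[:, None] + sd[:, None] * rng.standard_normal((config.n_genes, n)), 0.0
    )
    is_low = (true_labels.to_numpy() == "low")

    if config.senescence_d != 0.0:
        sig_noise = rng.standard_normal((sig_idx.size, n))
        eta = rng.standard_normal(n)
        if config.coupling_rho != 0.0:
            scores, _ = simulate_activity_scores(config)
            w = _calibrate_latent_weight(
                config, scores.to_numpy(), values, sig_idx,
                base[sig_idx], sd[sig_idx], sig_noise, is_low, eta,
                gene_ids, signature,
            )
        else:
            w = 0.0
        values[sig_idx] = _build_signature_block(
            base[sig_idx], sd[sig_idx], sig_noise, is_low, eta,
            config.senescence_d, w,
        )
    else:
        w = 0.0
        if config.coupling_rho != 0.0:
            logger.warning(
                "coupling_rho ignored: senescence_d is zero, no programme to couple"
            )

    return pd.DataFrame(values, index=gene_ids, columns=true_labels.index), w


def simulate_clinical(
    config: SyntheticCohortConfig,
    true_labels: pd.Series,
) -> pd.DataFrame:
    """Clinical table: age (years), sex, stage string, binary covariates.

    Each covariate named in ``clinical_or`` is Bernoulli with success
    probability 0.5 in the high group and odds multiplied by the mapped
    odds ratio in the low group, so the expected 2x2 odds ratio of
    covariate level vs low-group membership equals the configured value.
    Ages are uniform over 18-90 years; stage strings are sampled
    uniformly from common dialect spellings, independent of group.
    """
    n = config.n_samples
    if len(true_labels) != n:
        raise ValueError("true_labels length does not match n_samples")
    rng = _rng(config, "clinical")
    is_low = true_labels.to_numpy() == "low"
    table = pd.DataFrame(index=true_labels.index)
    table["age"] = rng.integers(18, 91, size=n)
    table["stage"] = rng.choice(_STAGE_DIALECTS, size=n)
    for cov, or_ in dict(config.clinical_or).items():
        if or_ <= 0:
            raise ValueError(f"odds ratio for {cov!r} must be positive")
        p_high = 0.5
        odds_low = or_ * p_high / (1.0 - p_high)
        p_low = odds_low / (1.0 + odds_low)
        p = np.where(is_low, p_low, p_high)
        table[cov] = (rng.random(n) < p).astype(int)
    if "sex_female" in table.columns:
        table["sex"] = np.where(table["sex_female"] == 1, "female", "male")
    else:
        table["sex"] = np.where(rng.random(n) < 0.5, "female", "male")
    return table


def simulate_genomic_features(
    config: SyntheticCohortConfig,
    true_labels: pd.Series,
) -> pd.DataFrame:
    """Genomic-instability covariates with group-dependent locations.

    TMB is negative binomial (group mean, shared dispersion); CNA and
    LOH fractions are Beta with group-dependent means at a shared
    concentration; the telomere-length tumour/normal ratio is log-normal
    with a group-dependent median.
    """
    n = config.n_samples
    if len(true_labels) != n:
        raise ValueError("true_labels length does not match n_samples")
    rng = _rng(config, "genomic")
    is_low = true_labels.to_numpy() == "low"

    tmb_mean = np.where(is_low, config.tmb_mean_low, config.tmb_mean_high)
    disp = config.tmb_dispersion
    tmb = rng.negative_binomial(disp, disp / (disp + tmb_mean))

    def beta_draw(mean_low: float, mean_high: float) -> np.ndarray:
        mean = np.where(is_low, mean_low, mean_high)
        kappa = config.cna_concentration
        return rng.beta(mean * kappa, (1.0 - mean) * kappa)

    cna = beta_draw(config.cna_mean_low, config.cna_mean_high)
    loh = beta_draw(config.loh_mean_low, config.loh_mean_high)
    tl_median = np.where(is_low, config.tl_median_low, config.tl_median_high)
    tl = np.exp(np.log(tl_median) + config.tl_sigma * rng.standard_normal(n))
    return pd.DataFrame(
        {"tmb": tmb, "cna_fraction": cna, "loh_fraction": loh, "tl_ratio": tl},
        index=true_labels.index,
    )


def simulate_single_cells(config: SyntheticCohortConfig) -> SingleCellMatrix:
    """Sparse count matrix with cycling/non-cycling cells.

    Exactly ``round(frac_cycling * n_cells)`` cells are flagged cycling.
    Counts are Poisson around per-gene base rates; cycling cells express
    the activity programme at a fixed 3-fold elevation while non-cycling
    cells express the senescence signature at a ``(1 + senescence_d)``-
    fold elevation (so a null senescence effect removes the signature
    contrast entirely).
    """
    if config.n_cells < 10:
        raise ValueError("n_cells must be at least 10")
    rng = _rng(config, "cells")
    n_cells = config.n_cells
    n_cyc = int(round(config.frac_cycling * n_cells))
    if n_cyc == 0 or n_cyc == n_cells:
        raise ValueError("frac_cycling leaves one cell population empty")
    cycling = np.array([True] * n_cyc + [False] * (n_cells - n_cyc))
    rng.shuffle(cycling)

    gene_ids = _gene_ids(config.n_genes)
    signature, activity = _planted_gene_sets(config)
    sig_mask = np.isin(np.asarray(gene_ids, dtype=object), np.asarray(signature.genes, dtype=object))
    act_mask = np.isin(np.asarray(gene_ids, dtype=object), np.asarray(activity.genes, dtype=object))

    lam = rng.lognormal(mean=math.log(0.3), sigma=1.0, size=config.n_genes)
    rates = np.repeat(lam[:, None], n_cells, axis=1)
    rates[np.ix_(act_mask, cycling)] *= 3.0
    rates[np.ix_(sig_mask, ~cycling)] *= 1.0 + config.senescence_d
    counts = rng.poisson(rates)
    cell_ids = [f"C{i + 1:05d}" for i in range(n_cells)]
    return SingleCellMatrix(
        gene_ids=gene_ids, cell_ids=cell_ids, counts=counts, cycling=cycling
    )


def simulate_cohort(
    config: SyntheticCohortConfig,
    include_cells: bool = True,
) -> SyntheticCohort:
    """Generate the full cohort bundle from one configuration."""
    scores, labels = simulate_activity_scores(config)
    expression, latent_w = _simulate_expression_impl(config, labels)
    clinical = simulate_clinical(config, labels)
    genomic = simulate_genomic_features(config, labels)
    cells = simulate_single_cells(config) if include_cells else None
    signature, activity = _planted_gene_sets(config)
    return SyntheticCohort(
        scores=scores,
        true_labels=labels,
        expression=expression,
        signature_genes=signature,
        activity_genes=activity,
        clinical=clinical,
        genomic=genomic,
        cells=cells,
        latent_weight=latent_w,
        config=config,
    )


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write every cohort table in its plain-text interchange format."""
    from . import io as tio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tio.write_scores_tsv(cohort.scores, out / "activity_scores.tsv", name="activity_score")
    cohort.true_labels.to_frame().to_csv(out / "true_labels.tsv", sep="\t")
    tio.write_expression_tsv(cohort.expression, out / "expression.tsv")
    tio.write_gmt(
        [cohort.signature_genes, cohort.activity_genes],
        out / "gene_sets.gmt",
        description="planted",
    )
    cohort.clinical.to_csv(out / "clinical.tsv", sep="\t")
    cohort.genomic.to_csv(out / "genomic.tsv", sep="\t", float_format="%.6g")
    if cohort.cells is not None:
        tio.write_mtx_dir(cohort.cells, out / "cells")
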