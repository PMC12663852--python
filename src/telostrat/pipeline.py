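"""Cohort-construction rules and the end-to-end analysis run.

The pipeline chains the stages of the stratification workflow:
simulate (optional) -> stratify activity scores -> score gene sets ->
stratify pathway scores -> compare feature families (clinical, genomic,
pathway scores) -> cross-tabulate binary activity states.  Everything is
deterministic given the configured seed, and outputs are plain TSV/JSON
so two runs of the same configuration are byte-identical.

Also housed here are the cohort-grouping conventions used throughout:
age schemes (clinical YA 18-50 / OA >50, or AYA 15-39 / OA >39, with
under-range samples excluded-with-flag rather than dropped), tumour
stage harmonisation (sub-stage letters stripped, I-II -> low-stage,
III-IV -> high-stage), and the recurrence filters for mutations (present
in >= 2 cancer types) and fusions (present in strictly more than 1 % of
samples per cancer type).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as tio
from .association import compare_features
from .sigscore import aucell_score, ssgsea_score
from .stratify import StratifiedCohort, consensus_stratify, stratify_scores_generic
from .synthetic import SyntheticCohortConfig, simulate_cohort

__all__ = [
    "CohortGroupingRules",
    "RecurrenceRules",
    "StateCrossTab",
    "assign_age_groups",
    "harmonize_stage",
    "filter_recurrent_mutations",
    "filter_frequent_fusions",
    "cross_tabulate_states",
    "run_pipeline",
    "default_config",
]

EXCLUDED = "excluded"


@dataclass
class CohortGroupingRules:
    """Age schemes, minimum group sizes, and the stage dichotomy."""

    age_scheme: str = "clinical"  # "clinical": YA 18-50 / OA >50; "aya": AYA 15-39 / OA >39
    min_group_n: int = 15
    min_cohort_n: int = 50

    def __post_init__(self) -> None:
        if self.age_scheme not in ("clinical", "aya"):
            raise ValueError(f"unknown age scheme {self.age_scheme!r}")
        if self.min_group_n <= 0 or self.min_cohort_n <= 0:
            raise ValueError("group-size thresholds must be positive")


@dataclass
class RecurrenceRules:
    """Thresholds for recurrent mutations and frequent fusions."""

    min_cancer_types: int = 2
    min_sample_fraction: float = 0.01  # strict ">" when applied
    top_n_genes: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.min_sample_fraction < 1.0):
            raise ValueError("min_sample_fraction must lie strictly between 0 and 1")
        if self.min_cancer_types < 1 or self.top_n_genes < 1:
            raise ValueError("count thresholds must be positive")


@dataclass
class StateCrossTab:
    """Counts of every observed combination of binary state axes."""

    axes: list[str]
    counts: pd.DataFrame  # one column per axis plus "count"

    def total(self) -> int:
        return int(self.counts["count"].sum())


def assign_age_groups(ages, scheme: str = "clinical") -> pd.Series:
    """Map ages in years to the configured two-group scheme.

    ``clinical``: 18 <= age <= 50 -> YA, age > 50 -> OA; ``aya``:
    15 <= age <= 39 -> AYA, age > 39 -> OA.  Ages below the lower bound
    are labelled ``excluded`` (kept, flagged) so partitions stay
    exhaustive; negative ages are an error.
    """
    ages = pd.Series(ages) if not isinstance(ages, pd.Series) else ages
    values = ages.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("ages must be non-negative")
    if scheme == "clinical":
        young_label, lo, hi = "YA", 18, 50
    elif scheme == "aya":
        young_label, lo, hi = "AYA", 15, 39
    else:
        raise ValueError(f"unknown age scheme {scheme!r}")
    out = np.where(
        values < lo, EXCLUDED, np.where(values <= hi, young_label, "OA")
    )
    return pd.Series(out, index=ages.index, name="age_group")


_STAGE_RE = re.compile(r"^(IV|III|II|I)")


def harmonize_stage(stage_strings) -> pd.Series:
    """Normalise stage dialects and collapse to low-stage / high-stage.

    Sub-stage letters and case are stripped ("Stage IIa" -> II); stages
    I-II map to ``low-stage``, III-IV to ``high-stage``; anything
    unparsable becomes ``unknown`` rather than being dropped.
    """
    s = pd.Series(stage_strings) if not isinstance(stage_strings, pd.Series) else stage_strings

    def _one(raw) -> str:
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            return "unknown"
        text = str(raw).strip().upper()
        text = re.sub(r"^STAGE\s*", "", text)
        m = _STAGE_RE.match(text)
        if not m:
            return "unknown"
        return "low-stage" if m.group(1) in ("I", "II") else "high-stage"

    return pd.Series([_one(v) for v in s], index=s.index, name="stage_group")


def filter_recurrent_mutations(
    presence: pd.DataFrame,
    rules: RecurrenceRules | None = None,
) -> tuple[list[str], list[str]]:
    """Partition mutated genes into recurrent and cancer-specific sets.

    ``presence`` is a gene x cancer-type boolean table.  Genes present in
    at least ``min_cancer_types`` cancers are recurrent; genes present in
    exactly one are cancer-specific; genes present nowhere are outside
    the partition (they are not mutated at all).
    """
    rules = rules or RecurrenceRules()
    if presence.empty:
        return [], []
    counts = presence.astype(bool).sum(axis=1)
    recurrent = [str(g) for g in counts.index[counts >= rules.min_cancer_types]]
    specific = [str(g) for g in counts.index[counts == 1]]
    return recurrent, specific


def filter_frequent_fusions(
    fusion_counts: pd.DataFrame,
    cohort_sizes: pd.Series,
    rules: RecurrenceRules | None = None,
) -> dict[str, list[str]]:
    """Keep, per cancer type, fusions present in > min_sample_fraction of samples.

    The threshold is a strict inequality: a fusion in exactly 1 % of
    samples is dropped under the default rule.
    """
    rules = rules or RecurrenceRules()
    kept: dict[str, list[str]] = {}
    for cancer in fusion_counts.columns:
        n = cohort_sizes.get(cancer)
        if n is None or n == 0:
            raise ValueError(f"cohort size missing or zero for {cancer!r}")
        col = fusion_counts[cancer]
        if (col > n).any():
            raise ValueError(f"fusion counts exceed cohort size for {cancer!r}")
        frac = col / float(n)
        kept[str(cancer)] = [str(f) for f in col.index[frac > rules.min_sample_fraction]]
    return kept


def cross_tabulate_states(
    stratifications: Mapping[str, StratifiedCohort],
    flags: Optional[Mapping[str, pd.Series]] = None,
) -> StateCrossTab:
    """Count every observed combination of low/high axes (plus binary flags)."""
    if not stratifications:
        raise ValueError("at least one stratification axis is required")
    columns: dict[str, pd.Series] = {}
    ref_ids: Optional[list[str]] = None
    for name, strat in stratifications.items():
        s = strat.groups_series()
        if ref_ids is None:
            ref_ids = list(s.index)
        elif set(s.index) != set(ref_ids):
            raise ValueError(f"axis {name!r} has mismatched sample ids")
        columns[name] = s.loc[ref_ids]
    if flags:
        for name, flag in flags.items():
            if set(flag.index) != set(ref_ids):
                raise ValueError(f"flag {name!r} has mismatched sample ids")
            columns[name] = flag.loc[ref_ids].map({True: "yes", False: "no"})
    frame = pd.DataFrame(columns)
    axes = list(frame.columns)
    counts = (
        frame.groupby(axes, observed=True)
        .size()
        .reset_index(name="count")
        .sort_values(axes, kind="stable")
        .reset_index(drop=True)
    )
    return StateCrossTab(axes=axes, counts=counts)


# --------------------------------------------------------------------------
# end-to-end run


def default_config() -> dict:
    """The bundled default run configuration (shipped as package data)."""
    from importlib.resources import files

    return json.loads(files("telostrat").joinpath("data/default_config.json").read_text())


def _derive_seeds(seed: int) -> dict[str, int]:
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    return {
        "simulate": int(rng.integers(2**31)),
        "stratify": int(rng.integers(2**31)),
    }


def run_pipeline(config: dict | str | Path, out_dir=None):
    """Execute the full simulate -> stratify -> score -> compare run.

    Parameters
    ----------
    config : dict or path to a JSON document
        Keys: ``seed``; ``simulate`` (SyntheticCohortConfig fields plus
        ``include_cells``); ``stratify`` (``n_iter``, ``n_init``);
        ``score`` (``method``: ssgsea or aucell, plus engine params);
        ``compare`` (``tl_test``: welch_t or wilcoxon); ``rules``
        (``age_scheme``).
    out_dir : path, optional
        If given, every stage table plus a JSON summary and plain-text
        log are written there.

    Returns
    -------
    PipelineReport with the stratification, scores, per-family
    comparison tables, and the state cross-tabulation.
    """
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    log: list[str] = []
    seed = int(config.get("seed", 0))
    seeds = _derive_seeds(seed)

    sim_cfg = dict(config.get("simulate", {}))
    include_cells = bool(sim_cfg.pop("include_cells", False))
    sim_cfg.setdefault("seed", seeds["simulate"])
    try:
        cohort = simulate_cohort(SyntheticCohortConfig(**sim_cfg), include_cells=include_cells)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    log.append(f"simulate: n={cohort.config.n_samples} genes={cohort.config.n_genes} "
               f"latent_weight={cohort.latent_weight:.4f}")

    strat_cfg = config.get("stratify", {})
    n_iter = int(strat_cfg.get("n_iter", 1000))
    n_init = int(strat_cfg.get("n_init", 50))
    try:
        strat = consensus_stratify(
            cohort.scores, n_iter=n_iter, n_init=n_init, seed=seeds["stratify"]
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'stratify' failed: {exc}") from exc
    log.append(f"stratify: n_runs={strat.n_runs} boundary={strat.boundary:.4f} "
               f"n_low={int(np.sum(strat.group == 'low'))} "
               f"n_high={int(np.sum(strat.group == 'high'))}")

    score_cfg = config.get("score", {})
    method = score_cfg.get("method", "ssgsea")
    try:
        if method == "ssgsea":
            sen = ssgsea_score(
                cohort.expression, cohort.signature_genes,
                alpha=float(score_cfg.get("alpha", 0.25)),
            )
        elif method == "aucell":
            sen = aucell_score(
                cohort.expression, cohort.signature_genes,
                top_fraction=float(score_cfg.get("top_fraction", 0.05)),
            )
        else:
            raise ValueError(f"unknown bulk scoring method {method!r}")
        sen_series = sen.to_series().rename("senescence")
        path_strats = stratify_scores_generic(
            {"senescence": sen_series}, n_iter=n_iter, n_init=n_init,
            seed=seeds["stratify"],
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'score' failed: {exc}") from exc
    log.append(f"score: method={method} gene_set={cohort.signature_genes.name}")

    rules = CohortGroupingRules(
        age_scheme=config.get("rules", {}).get("age_scheme", "clinical")
    )
    compare_cfg = config.get("compare", {})
    tl_test = compare_cfg.get("tl_test", "wilcoxon")

    try:
        age_groups = assign_age_groups(cohort.clinical["age"], rules.age_scheme)
        stage_groups = harmonize_stage(cohort.clinical["stage"])
        clin_feats = pd.DataFrame(index=cohort.clinical.index)
        binary_covs = [
            c for c in cohort.clinical.columns
            if c not in ("age", "sex", "stage")
        ]
        for c in binary_covs:
            clin_feats[c] = cohort.clinical[c]
        old_label = "OA"
        clin_feats["age_older"] = np.where(
            age_groups == EXCLUDED, np.nan, (age_groups == old_label).astype(float)
        )
        clin_feats["stage_high"] = np.where(
            stage_groups == "unknown", np.nan, (stage_groups == "high-stage").astype(float)
        )
        clin_plan = {c: "fisher" for c in clin_feats.columns}
        clinical_cmp = compare_features(clin_feats, strat, clin_plan)

        gen_plan = {
            "tmb": "wilcoxon",
            "cna_fraction": "welch_t",
            "loh_fraction": "welch_t",
            "tl_ratio": tl_test,
        }
        genomic_cmp = compare_features(cohort.genomic, strat, gen_plan)

        score_feats = sen_series.to_frame()
        score_cmp = compare_features(score_feats, strat, {"senescence": "welch_t"})
    except Exception as exc:
        raise RuntimeError(f"stage 'compare' failed: {exc}") from exc
    log.append(
        "compare: families clinical=%d genomic=%d scores=%d"
        % (len(clinical_cmp), len(genomic_cmp), len(score_cmp))
    )

    try:
        crosstab = cross_tabulate_states({"telomerase": strat, **{
            name: s for name, s in path_strats.items()
        }})
    except Exception as exc:
        raise RuntimeError(f"stage 'crosstab' failed: {exc}") from exc
    log.append(f"crosstab: axes={crosstab.axes} total={crosstab.total()}")

    report = PipelineReport(
        cohort=cohort,
        stratification=strat,
        senescence_scores=sen_series,
        pathway_stratifications=path_strats,
        comparisons={
            "clinical": clinical_cmp,
            "genomic": genomic_cmp,
            "scores": score_cmp,
        },
        crosstab=crosstab,
        seed=seed,
        log=log,
    )
    if out_dir is not None:
        report.write(out_dir, config)
    return report


@dataclass
class PipelineReport:
    """All artefacts of one pipeline run."""

    cohort: object
    stratification: StratifiedCohort
    senescence_scores: pd.Series
    pathway_stratifications: dict[str, StratifiedCohort]
    comparisons: dict[str, pd.DataFrame]
    crosstab: StateCrossTab
    seed: int
    log: list[str] = field(default_factory=list)

    def all_comparisons(self) -> pd.DataFrame:
        frames = []
        for family, df in self.comparisons.items():
            df = df.copy()
            df.insert(0, "family", family)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def write(self, out_dir, config: dict | None = None) -> None:
        from . import __version__

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tio.write_groups_tsv(self.stratification, out / "groups.tsv")
        tio.write_scores_tsv(
            self.senescence_scores, out / "senescence_scores.tsv", name="senescence"
        )
        for family, df in self.comparisons.items():
            df.to_csv(out / f"comparisons_{family}.tsv", sep="\t", index=False,
                      float_format="%.10g")
        self.crosstab.counts.to_csv(out / "crosstab.tsv", sep="\t", index=False)
        summary = {
            "seed": self.seed,
            "version": __version__,
            "stratification": self.stratification.summary(),
            "pathway_axes": {
                k: v.summary() for k, v in self.pathway_stratifications.items()
            },
            "config": config,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        (out / "run_log.txt").write_text("\n".join(self.log) + "\n")
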