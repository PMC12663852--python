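"""Group-association statistics for stratified cohorts.

The battery mirrors the tests used when comparing low- against
high-activity tumour groups: Fisher's exact test with a cross-product
odds ratio for binary covariates, Welch's t-test with Cohen's d for
continuous features, the Wilcoxon rank-sum test with the Hodges-Lehmann
shift estimate for skewed features such as tumour mutation burden,
Spearman rank correlation for score-score coupling, and
Benjamini-Hochberg FDR control applied once per submitted feature
family.

Odds ratios are sample cross-product ratios with a Haldane +0.5
correction on zero cells (matching how large odds ratios are typically
reported from count tables), not conditional maximum-likelihood
estimates.  Effect signs are oriented high-minus-low for continuous
features, so a positive effect means enrichment in the high-activity
group.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stratify import StratifiedCohort

logger = logging.getLogger(__name__)

__all__ = [
    "fisher_exact_2x2",
    "welch_t",
    "wilcoxon_rank_sum",
    "spearman_corr",
    "bh_fdr",
    "compare_features",
]

# largest combined sample size for which the rank-sum p-value is computed
# by exact enumeration (ties force the normal approximation regardless)
WILCOXON_EXACT_MAX_N = 12


def _check_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("contingency table must be 2x2")
    if (t < 0).any() or not np.all(t == np.round(t)):
        raise ValueError("table entries must be non-negative integers")
    if t.sum() < 1:
        raise ValueError("table total must be at least 1")
    return t


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test and cross-product odds ratio.

    The p-value sums hypergeometric probabilities (margins fixed) of all
    tables at most as probable as the observed one.  The odds ratio is
    ``(a*d)/(b*c)`` with a Haldane +0.5 correction added to every cell
    iff any cell is zero.  A zero row or column margin carries no
    association information: p = 1 and the odds ratio is NaN.
    """
    t = _check_table(table)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0, float("nan")
    p = float(stats.fisher_exact(t.astype(int), alternative="two-sided")[1])
    a, b, c, d = t.ravel()
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return p, float((a * d) / (b * c))


def _pooled_sd(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = x.size, y.size
    return float(
        np.sqrt(
            ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
        )
    )


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's two-sided t-test with Cohen's d.

    Returns ``(t, p, d)`` where ``t`` uses Satterthwaite degrees of
    freedom and ``d = (mean(x) - mean(y)) / s_pooled`` with the standard
    (n-1)-weighted pooled standard deviation.  Two identical constant
    groups return ``(0, 1, 0)``; two different constant groups have an
    infinite standardised difference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t requires at least 2 observations per group")
    sp = _pooled_sd(x, y)
    diff = float(x.mean() - y.mean())
    if sp == 0.0:
        if diff == 0.0:
            return 0.0, 1.0, 0.0
        return float(np.inf) * np.sign(diff), 0.0, float(np.inf) * np.sign(diff)
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue), diff / sp


def wilcoxon_rank_sum(x, y) -> tuple[float, float, float]:
    """Wilcoxon rank-sum test with the Hodges-Lehmann shift estimate.

    Returns ``(W, p, hl)`` where ``W`` is the rank sum of ``x`` in the
    combined sample (average ranks on ties), ``p`` is two-sided -- exact
    by enumeration when ``len(x) + len(y) <= 12`` with no ties, otherwise
    a tie-corrected normal approximation with continuity correction --
    and ``hl`` is the median of all pairwise differences ``x_i - y_j``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum requires non-empty groups")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    exact = (x.size + y.size) <= WILCOXON_EXACT_MAX_N and not has_ties
    res = stats.mannwhitneyu(
        x, y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    w = float(res.statistic + x.size * (x.size + 1) / 2)  # U -> rank sum of x
    hl = float(np.median(np.subtract.outer(x, y)))
    return w, float(res.pvalue), hl


def spearman_corr(u, v) -> tuple[float, float]:
    """Spearman rank correlation with a t-approximation p-value (n-2 df).

    Either vector being constant leaves the correlation undefined:
    ``(nan, nan)`` is returned with a logged warning.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.size != v.size:
        raise ValueError("vectors must have equal length")
    if u.size < 4:
        raise ValueError("spearman_corr requires at least 4 observations")
    if np.unique(u).size < 2 or np.unique(v).size < 2:
        logger.warning("spearman_corr: constant input vector; correlation undefined")
        return float("nan"), float("nan")
    res = stats.spearmanr(u, v)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``q_(i) = min_{j >= i} (m * p_(j) / j)`` clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


_CONTINUOUS_TESTS = {"welch_t", "wilcoxon"}
_VALID_TESTS = _CONTINUOUS_TESTS | {"fisher", "spearman"}


def compare_features(
    features: pd.DataFrame,
    cohort: StratifiedCohort,
    test_plan: Mapping[str, str],
    scores: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Run the mapped test per feature, low vs high group, with one BH family.

    Parameters
    ----------
    features : DataFrame indexed by sample id
        One column per feature.  ``fisher`` features must be binary
        (0/1 or boolean); continuous tests compare the high against the
        low group (positive effect = enriched in the high group);
        ``spearman`` correlates the feature with ``scores`` (required).
    cohort : StratifiedCohort
        Low/high labels from :func:`telostrat.stratify.consensus_stratify`.
    test_plan : mapping feature -> {"fisher", "welch_t", "wilcoxon", "spearman"}
    scores : Series, optional
        Underlying continuous activity scores, needed for ``spearman``.

    Returns
    -------
    DataFrame with columns feature_id, test, statistic, effect, p, q,
    n_low, n_high, direction.  BH correction is applied once across all
    features submitted in this call (one family per battery).
    """
    groups = cohort.groups_series()
    missing_ids = [i for i in features.index if i not in groups.index]
    if missing_ids:
        raise ValueError(f"features contain unknown sample ids: {missing_ids[:5]}")
    rows = []
    for feat, test in test_plan.items():
        if test not in _VALID_TESTS:
            raise ValueError(f"unknown test {test!r} for feature {feat!r}")
        if feat not in features.columns:
            raise ValueError(f"feature {feat!r} not found in the feature table")
        col = features[feat]
        valid = col.notna()
        if not valid.any():
            logger.warning("feature %s: all values missing; skipped", feat)
            continue
        col = col[valid]
        grp = groups.loc[col.index]
        lo = col[grp == "low"].to_numpy(dtype=float)
        hi = col[grp == "high"].to_numpy(dtype=float)
        n_low, n_high = lo.size, hi.size
        if test == "fisher":
            vals = set(np.unique(col.astype(float)))
            if not vals <= {0.0, 1.0}:
                raise ValueError(f"feature {feat!r} is not binary; fisher needs 0/1")
            table = [
                [int((lo == 1).sum()), int((lo == 0).sum())],
                [int((hi == 1).sum()), int((hi == 0).sum())],
            ]
            p, or_ = fisher_exact_2x2(table)
            stat, effect = or_, or_
            if not np.isfinite(or_) or or_ == 1.0:
                direction = "none"
            elif or_ > 1.0:
                direction = "low_enriched"  # level enriched in the low group
            else:
                direction = "high_enriched"
        elif test == "welch_t":
            stat, p, effect = welch_t(hi, lo)
            direction = _sign_direction(effect)
        elif test == "wilcoxon":
            stat, p, effect = wilcoxon_rank_sum(hi, lo)
            direction = _sign_direction(effect)
        else:  # spearman
            if scores is None:
                raise ValueError("spearman test requires the activity score vector")
            sc = scores.loc[col.index].to_numpy(dtype=float)
            rho, p = spearman_corr(sc, col.to_numpy(dtype=float))
            stat, effect = rho, rho
            if np.isnan(rho):
                p = 1.0
            direction = _sign_direction(effect)
        rows.append(
            {
                "feature_id": feat,
                "test": test,
                "statistic": stat,
                "effect": effect,
                "p": p,
                "q": np.nan,
                "n_low": n_low,
                "n_high": n_high,
                "direction": direction,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "feature_id", "test", "statistic", "effect",
            "p", "q", "n_low", "n_high", "direction",
        ],
    )
    if len(result):
        result["q"] = bh_fdr(result["p"].to_numpy())
    return result


def _sign_direction(effect: float) -> str:
    if not np.isfinite(effect) or effect == 0.0:
        return "none"
    return "high_enriched" if effect > 0 else "low_enriched"
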