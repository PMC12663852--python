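"""Consensus k-means stratification of one-dimensional activity scores.

A vector of per-sample telomerase-activity (or pathway-activity) scores
is classified into a ``low`` and a ``high`` group by running Lloyd's
k-means (k = 2) many times from random initial centroids and taking, per
sample, the majority label over all runs after orienting each run's
clusters by centroid order (larger centroid = ``high``).  The default
protocol aggregates 1000 x 50 = 50,000 partitions per score vector;
both counts are configurable so that test-scale runs stay cheap.

Compared with a fixed median split, the k-means boundary adapts to
non-uniform score distributions (skewed mixtures, unequal group sizes),
and the run-consensus quantifies per-sample assignment stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np
import pandas as pd

__all__ = [
    "StratifiedCohort",
    "kmeans_1d",
    "consensus_stratify",
    "stratify_scores_generic",
]

_MAX_LLOYD_ITER = 10_000
# cap on boolean assignment-matrix entries held per Lloyd batch (~40 MB)
_BATCH_CELLS = 40_000_000


class DegenerateScoresError(ValueError):
    """Raised when a score vector cannot support a 2-group split."""


@dataclass
class StratifiedCohort:
    """Low/high classification of a score vector with per-sample consensus.

    Attributes
    ----------
    sample_ids, group:
        Per-sample label, ``"low"`` or ``"high"``.
    consensus_fraction:
        Share of runs agreeing with the final label, in [0.5, 1].
    boundary:
        Midpoint between the maximal low-assigned and the minimal
        high-assigned score (NaN if either group is empty).
    n_runs:
        Total number of aggregated k-means partitions.
    centroids:
        (mean of low-group scores, mean of high-group scores).
    tie_flags:
        True where the vote was an exact 0.5 tie (labelled ``low``).
    """

    sample_ids: list[str]
    group: np.ndarray
    consensus_fraction: np.ndarray
    boundary: float
    n_runs: int
    centroids: tuple[float, float]
    tie_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.tie_flags is None:
            self.tie_flags = np.zeros(len(self.sample_ids), dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "group": self.group,
                "consensus_fraction": self.consensus_fraction,
            }
        )

    def groups_series(self) -> pd.Series:
        return pd.Series(self.group, index=pd.Index(self.sample_ids), name="group")

    def summary(self) -> dict:
        return {
            "n_samples": len(self.sample_ids),
            "n_low": int(np.sum(self.group == "low")),
            "n_high": int(np.sum(self.group == "high")),
            "boundary": self.boundary,
            "centroids": {"low": self.centroids[0], "high": self.centroids[1]},
            "n_runs": self.n_runs,
            "n_vote_ties": int(self.tie_flags.sum()),
        }


def _as_scores(scores) -> tuple[list[str], np.ndarray]:
    if isinstance(scores, pd.Series):
        ids = [str(i) for i in scores.index]
        values = scores.to_numpy(dtype=float)
    else:
        values = np.asarray(scores, dtype=float)
        ids = [f"s{i + 1}" for i in range(values.size)]
    if values.ndim != 1:
        raise ValueError("scores must be one-dimensional")
    if len(set(ids)) != len(ids):
        raise ValueError("sample ids must be unique")
    if not np.isfinite(values).all():
        raise ValueError("scores must be finite")
    return ids, values


def _lloyd_batch(x: np.ndarray, init: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run Lloyd's algorithm for k=2 on 1-D data for a batch of runs.

    ``init`` is (R, 2) initial centroids.  Returns the boolean assignment
    matrix (R, n; True = upper cluster) and the two centroid vectors.
    Assignment is by nearest centroid, i.e. a threshold at the centroid
    midpoint with points exactly on the threshold joining the upper
    cluster; iteration stops when assignments are unchanged.
    """
    n = x.size
    total = x.sum()
    c = np.sort(np.asarray(init, dtype=float), axis=1)
    c_lo, c_hi = c[:, 0].copy(), c[:, 1].copy()
    thr = 0.5 * (c_lo + c_hi)
    assign = x[None, :] >= thr[:, None]
    for _ in range(_MAX_LLOYD_ITER):
        n_hi = assign.sum(axis=1)
        # empty-cluster guard: reseed the empty centroid at the point
        # farthest from the surviving centroid (unreachable when initial
        # centroids are distinct observed values, kept for safety)
        empty_lo = n_hi == n
        empty_hi = n_hi == 0
        if empty_lo.any():
            far = x[np.argmax(np.abs(x[None, :] - c_hi[empty_lo, None]), axis=1)]
            thr_fix = 0.5 * (far + c_hi[empty_lo])
            assign[empty_lo] = x[None, :] >= thr_fix[:, None]
            n_hi = assign.sum(axis=1)
        if empty_hi.any():
            far = x[np.argmax(np.abs(x[None, :] - c_lo[empty_hi, None]), axis=1)]
            thr_fix = 0.5 * (c_lo[empty_hi] + far)
            assign[empty_hi] = x[None, :] >= thr_fix[:, None]
            n_hi = assign.sum(axis=1)
        s_hi = assign @ x
        c_hi = s_hi / n_hi
        c_lo = (total - s_hi) / (n - n_hi)
        thr = 0.5 * (c_lo + c_hi)
        new = x[None, :] >= thr[:, None]
        if np.array_equal(new, assign):
            return assign, c_lo, c_hi
        assign = new
    raise RuntimeError("Lloyd iteration failed to converge")


def kmeans_1d(
    scores,
    k: int = 2,
    seed: int | None = None,
) -> tuple[np.ndarray, tuple[float, float], float]:
    """One Lloyd's k-means run on a 1-D score vector.

    Initial centroids are ``k`` distinct observed values sampled
    uniformly without replacement, which guarantees non-empty starting
    clusters.  Returns ``(partition, centroids, within_ss)`` where
    ``partition`` assigns 0 to the lower-centroid cluster and 1 to the
    upper one, ``centroids`` is ordered ``(low, high)``, and
    ``within_ss`` is the total within-cluster sum of squares.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if k != 2:
        raise NotImplementedError("only k = 2 (low/high) classification is supported")
    _, x = _as_scores(scores)
    uniq = np.unique(x)
    if uniq.size < k:
        raise DegenerateScoresError(
            f"need at least {k} distinct score values, got {uniq.size}"
        )
    rng = np.random.default_rng(seed)
    init = rng.choice(uniq, size=k, replace=False)
    assign, c_lo, c_hi = _lloyd_batch(x, init[None, :])
    part = assign[0].astype(int)
    lo, hi = float(c_lo[0]), float(c_hi[0])
    within_ss = float(np.sum((x - np.where(part == 1, hi, lo)) ** 2))
    return part, (lo, hi), within_ss


def consensus_stratify(
    scores,
    n_iter: int = 1000,
    n_init: int = 50,
    seed: int | None = None,
    method: str = "majority",
) -> StratifiedCohort:
    """Classify scores into low/high groups by consensus over many k-means runs.

    ``n_iter`` consensus rounds are executed.  Each round runs Lloyd's
    algorithm from ``n_init`` fresh pairs of distinct observed values
    (all drawn from a single seeded stream) and keeps the partition with
    the smallest within-cluster sum of squares -- the standard
    multiple-restart k-means rule, which makes each round's partition the
    global optimum with overwhelming probability.  Within each kept
    partition the cluster with the larger centroid is labelled ``high``;
    the final per-sample label is the majority vote over the ``n_iter``
    kept partitions (exact 0.5 ties go to ``low`` and are flagged) and
    ``consensus_fraction`` records the agreeing share of rounds.
    ``n_runs`` reports the total number of Lloyd runs executed
    (``n_iter * n_init``).

    ``method="coassignment"`` is an alternative consensus rule that
    average-links the round-level co-assignment matrix and cuts it into
    two groups; it gives identical labels in ordinary 1-D practice at a
    much higher cost and is provided for cross-checking.
    """
    ids, x = _as_scores(scores)
    n = x.size
    if n < 4:
        raise DegenerateScoresError("need at least 4 samples to stratify")
    uniq = np.unique(x)
    if uniq.size < 2:
        raise DegenerateScoresError("scores are constant; no 2-group split exists")
    n_iter, n_init = int(n_iter), int(n_init)
    n_runs = n_iter * n_init
    if n_runs < 1:
        raise ValueError("n_iter * n_init must be at least 1")
    if method not in ("majority", "coassignment"):
        raise ValueError(f"unknown consensus method {method!r}")

    rng = np.random.default_rng(seed)
    # one distinct unordered pair of observed values per Lloyd run
    i_idx = rng.integers(uniq.size, size=n_runs)
    j_idx = rng.integers(uniq.size - 1, size=n_runs)
    j_idx = j_idx + (j_idx >= i_idx)
    inits = np.stack([uniq[i_idx], uniq[j_idx]], axis=1)

    sumsq = float(np.sum(x * x))
    votes_high = np.zeros(n)
    coassign = np.zeros((n, n)) if method == "coassignment" else None
    rounds_per_chunk = max(1, _BATCH_CELLS // max(n * n_init, 1))
    for start in range(0, n_iter, rounds_per_chunk):
        n_rounds = min(rounds_per_chunk, n_iter - start)
        batch_init = inits[start * n_init : (start + n_rounds) * n_init]
        assign, c_lo, c_hi = _lloyd_batch(x, batch_init)
        n_hi = assign.sum(axis=1)
        within = sumsq - n_hi * c_hi**2 - (n - n_hi) * c_lo**2
        best = np.argmin(within.reshape(n_rounds, n_init), axis=1)
        keep = assign.reshape(n_rounds, n_init, n)[np.arange(n_rounds), best]
        votes_high += keep.sum(axis=0)
        if coassign is not None:
            a = keep.astype(float)
            coassign += a.T @ a + (1 - a).T @ (1 - a)

    frac_high = votes_high / n_iter
    if method == "majority":
        high = frac_high > 0.5
        tie = frac_high == 0.5
    else:
        high = _cut_coassignment(coassign / n_iter, x)
        tie = frac_high == 0.5

    consensus = np.where(high, frac_high, 1.0 - frac_high)
    group = np.where(high, "high", "low")
    if high.all() or (~high).all():
        boundary = float("nan")
        centroids = (float(x[~high].mean()) if (~high).any() else float("nan"),
                     float(x[high].mean()) if high.any() else float("nan"))
    else:
        boundary = float(0.5 * (x[~high].max() + x[high].min()))
        centroids = (float(x[~high].mean()), float(x[high].mean()))
    return StratifiedCohort(
        sample_ids=ids,
        group=group,
        consensus_fraction=consensus,
        boundary=boundary,
        n_runs=n_runs,
        centroids=centroids,
        tie_flags=tie,
    )


def _cut_coassignment(mean_coassign: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Average-linkage cut of the mean co-assignment matrix into two groups."""
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    dist = 1.0 - mean_coassign
    np.fill_diagonal(dist, 0.0)
    dist = 0.5 * (dist + dist.T)  # symmetrise fp noise
    labels = fcluster(linkage(squareform(dist, checks=False), "average"), 2, "maxclust")
    means = [x[labels == g].mean() for g in (1, 2)]
    return labels == (2 if means[1] > means[0] else 1)


def stratify_scores_generic(
    score_table: Union[pd.DataFrame, Mapping[str, pd.Series]],
    n_iter: int = 1000,
    n_init: int = 50,
    seed: int | None = None,
) -> dict[str, StratifiedCohort]:
    """Apply :func:`consensus_stratify` independently to each named score vector.

    The same seed is used for every vector, so identical vectors under
    different names produce identical stratifications.  A degenerate
    vector raises an error naming the offending entry.
    """
    if isinstance(score_table, pd.DataFrame):
        items = [(str(c), score_table[c]) for c in score_table.columns]
    else:
        items = [(str(k), v) for k, v in score_table.items()]
    out: dict[str, StratifiedCohort] = {}
    for name, vec in items:
        try:
            out[name] = consensus_stratify(vec, n_iter=n_iter, n_init=n_init, seed=seed)
        except (DegenerateScoresError, ValueError) as exc:
            raise type(exc)(f"score vector {name!r}: {exc}") from exc
    return out
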