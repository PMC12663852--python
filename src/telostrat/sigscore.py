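"""Single-sample gene-set scoring engines.

Three engines are provided, matching the three data modalities of a
pan-cancer telomerase/senescence analysis:

``ssgsea_score``
    A weighted running-sum enrichment statistic for bulk expression
    profiles (one score per sample, computed from that sample's column
    alone).  The score is the integrated difference between the weighted
    in-set rank ECDF and the uniform out-of-set ECDF.

``jasmine_score``
    A rank-plus-enrichment composite for sparse single-cell counts where
    dropout makes dense rank statistics unreliable.  The score averages a
    normalised mean-rank component (over expressed genes only) and an
    odds-ratio enrichment component, each min-max scaled across cells.

``aucell_score``
    A recovery-curve AUC: the area under the cumulative signature-gene
    retrieval curve within the top-ranked fraction of a sample's genes,
    normalised so a perfect recovery scores 1.  Suited to spot-level
    spatial data and module activity calls.

All three engines depend on expression values only through within-sample
ranks (and zero/non-zero status for the single-cell engine), so they are
invariant under strictly increasing per-sample transforms and indifferent
to whether the input is on a raw, CPM, or log scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "SingleCellMatrix",
    "SignatureScores",
    "ssgsea_score",
    "jasmine_score",
    "aucell_score",
]


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (e.g. a 125-gene senescence signature)."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        if len(genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(genes)) != len(genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class SingleCellMatrix:
    """A gene-by-cell count matrix with explicit, meaningful zeros.

    ``cycling`` optionally carries a per-cell boolean cell-cycle flag
    (True = cycling), consumed as an annotation.
    """

    gene_ids: Sequence[str]
    cell_ids: Sequence[str]
    counts: Union[np.ndarray, sparse.spmatrix]
    cycling: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        shape = self.counts.shape
        if shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.dense().min() < 0:
            raise ValueError("counts must be non-negative")
        if self.cycling is not None:
            self.cycling = np.asarray(self.cycling, dtype=bool)
            if self.cycling.shape != (len(self.cell_ids),):
                raise ValueError("cycling flag length does not match cell count")

    def dense(self) -> np.ndarray:
        if sparse.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)


@dataclass
class SignatureScores:
    """Per-sample (or per-cell) signature scores from one engine."""

    ids: list[str]
    scores: np.ndarray
    method: str
    gene_set_name: str
    params: dict = field(default_factory=dict)

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=pd.Index(self.ids), name=self.gene_set_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "score": self.scores,
                "method": self.method,
                "gene_set": self.gene_set_name,
            }
        )


def _resolve_set(gene_ids: Sequence[str], gs: GeneSet) -> np.ndarray:
    """Boolean mask of set membership; warns about (and drops) absent genes."""
    index = {g: i for i, g in enumerate(gene_ids)}
    mask = np.zeros(len(gene_ids), dtype=bool)
    missing = []
    for g in gs.genes:
        i = index.get(g)
        if i is None:
            missing.append(g)
        else:
            mask[i] = True
    if missing:
        logger.warning(
            "gene set %s: %d/%d genes absent from the matrix were dropped",
            gs.name, len(missing), len(gs),
        )
    if not mask.any():
        raise ValueError(f"no gene of set {gs.name!r} is present in the matrix")
    return mask


def _expr_to_arrays(expr: Union[pd.DataFrame, SingleCellMatrix]):
    if isinstance(expr, SingleCellMatrix):
        return list(expr.gene_ids), list(expr.cell_ids), expr.dense().astype(float)
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    if expr.index.has_duplicates or expr.columns.has_duplicates:
        raise ValueError("expression matrix has duplicate gene or sample ids")
    return list(expr.index), list(expr.columns), values


def ssgsea_score(
    expr: pd.DataFrame,
    gs: GeneSet,
    alpha: float = 0.25,
) -> SignatureScores:
    """Single-sample enrichment score by a weighted running sum.

    For each sample, genes are walked in order of decreasing expression
    (ties broken by gene id for determinism).  At step ``i`` the statistic
    accumulates ``P_in(i) - P_out(i)`` where ``P_in`` is the cumulative
    in-set weight -- each in-set gene weighted by its ascending average
    rank raised to ``alpha``, normalised by the total in-set weight -- and
    ``P_out`` is the uniform ECDF over out-of-set genes.  The enrichment
    score is the sum over all steps (not the maximum deviation), so it is
    a single-sample statistic requiring no cross-sample normalisation.

    Parameters
    ----------
    expr : DataFrame, genes x samples
        Expression values on any scale; only within-sample ranks matter.
    gs : GeneSet
        Signature genes.  Genes absent from ``expr`` are dropped with a
        logged warning; a set covering all genes of the matrix is an error
        (the out-of-set ECDF would be empty).
    alpha : float
        Rank-weighting exponent for in-set genes.
    """
    gene_ids, sample_ids, values = _expr_to_arrays(expr)
    in_set = _resolve_set(gene_ids, gs)
    n_genes = len(gene_ids)
    n_out = n_genes - int(in_set.sum())
    if n_out == 0:
        raise ValueError("gene set covers every gene in the matrix (empty complement)")

    # secondary sort key: position of each gene in the id-sorted order
    id_key = np.argsort(np.argsort(np.asarray(gene_ids, dtype=object)))

    scores = np.empty(len(sample_ids))
    for j in range(len(sample_ids)):
        col = values[:, j]
        ranks = rankdata(col, method="average")  # ascending, ties -> average
        order = np.lexsort((id_key, -col))  # descending expression, stable by id
        inset_o = in_set[order]
        weights = np.where(inset_o, ranks[order] ** alpha, 0.0)
        p_in = np.cumsum(weights) / weights.sum()
        p_out = np.cumsum(~inset_o) / n_out
        scores[j] = float(np.sum(p_in - p_out))
    return SignatureScores(sample_ids, scores, "ssgsea", gs.name, {"alpha": alpha})


def jasmine_score(sc: SingleCellMatrix, gs: GeneSet) -> SignatureScores:
    """Rank/odds-ratio composite signature score for single-cell counts.

    Per cell: (i) the *rank component* is the mean ascending average rank
    of expressed (count > 0) set genes among all expressed genes of the
    cell, divided by the number of expressed genes (cells expressing no
    set gene score 0); (ii) the *enrichment component* is the odds ratio
    of the 2x2 table {set, non-set} x {expressed, not expressed}, with a
    Haldane +0.5 correction applied to all cells of the table when any
    entry is zero.  Each component is min-max scaled to [0, 1] across
    cells (a degenerate max == min range maps to 0 for every cell) and the
    final score is the arithmetic mean of the two scaled components.
    """
    gene_ids, cell_ids, counts = _expr_to_arrays(sc)
    if len(cell_ids) < 2:
        raise ValueError("jasmine_score requires at least 2 cells (min-max undefined)")
    if not counts.any():
        raise ValueError("all-zero count matrix")
    in_set = _resolve_set(gene_ids, gs)
    n_genes = len(gene_ids)
    set_size = int(in_set.sum())

    n_cells = len(cell_ids)
    rank_comp = np.zeros(n_cells)
    or_comp = np.zeros(n_cells)
    for j in range(n_cells):
        col = counts[:, j]
        expressed = col > 0
        n_expr = int(expressed.sum())
        set_expr = int((expressed & in_set).sum())
        if n_expr > 0 and set_expr > 0:
            ranks = rankdata(col[expressed], method="average")
            set_ranks = ranks[in_set[expressed]]
            rank_comp[j] = set_ranks.mean() / n_expr
        a = float(set_expr)
        b = float(set_size - set_expr)
        c = float(n_expr - set_expr)
        d = float((n_genes - set_size) - (n_expr - set_expr))
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        or_comp[j] = (a * d) / (b * c)

    def _minmax(v: np.ndarray) -> np.ndarray:
        lo, hi = v.min(), v.max()
        if hi == lo:
            return np.zeros_like(v)
        return (v - lo) / (hi - lo)

    scores = 0.5 * (_minmax(rank_comp) + _minmax(or_comp))
    return SignatureScores(cell_ids, scores, "jasmine", gs.name, {})


def aucell_score(
    expr: Union[pd.DataFrame, SingleCellMatrix],
    gs: GeneSet,
    top_fraction: float = 0.05,
) -> SignatureScores:
    """Recovery-curve AUC signature score.

    Per sample (or spot/cell): all genes are ordered by decreasing
    expression (ties resolved by average rank, then stably by gene id);
    over the top ``m = ceil(top_fraction * G)`` positions the cumulative
    count of recovered set genes traces a step curve whose area is
    normalised by the maximal achievable area (all ``min(|set|, m)`` set
    genes occupying the top positions), so scores lie in [0, 1].
    """
    if not (0.0 < top_fraction < 1.0):
        raise ValueError("top_fraction must lie strictly between 0 and 1")
    gene_ids, sample_ids, values = _expr_to_arrays(expr)
    in_set = _resolve_set(gene_ids, gs)
    n_genes = len(gene_ids)
    m = math.ceil(top_fraction * n_genes)
    if m < 1:
        raise ValueError("top fraction selects no genes")
    s_max = min(int(in_set.sum()), m)
    max_area = s_max * (s_max + 1) / 2 + s_max * (m - s_max)

    id_key = np.argsort(np.argsort(np.asarray(gene_ids, dtype=object)))
    scores = np.empty(len(sample_ids))
    for j in range(len(sample_ids)):
        col = values[:, j]
        order = np.lexsort((id_key, -col))
        hits = in_set[order][:m]
        scores[j] = float(np.cumsum(hits).sum() / max_area)
    return SignatureScores(
        sample_ids, scores, "aucell", gs.name, {"top_fraction": top_fraction}
    )
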