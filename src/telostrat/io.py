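"""Readers and writers for the plain-text formats the pipeline consumes.

Gene sets travel as GMT lines (set name, description, tab-separated gene
ids), bulk expression as TSV with genes in rows and a header row of
sample ids, single-cell counts as a MatrixMarket triplet with
``genes.tsv`` / ``barcodes.tsv`` sidecars, and scores/groups/feature
tables as keyed TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .sigscore import GeneSet, SingleCellMatrix
from .stratify import StratifiedCohort

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_scores_tsv",
    "write_scores_tsv",
    "write_groups_tsv",
    "read_groups_tsv",
    "read_mtx_dir",
    "write_mtx_dir",
]

PathLike = Union[str, Path]


def read_gmt(path: PathLike) -> list[GeneSet]:
    """Parse a GMT file: one gene set per line, name TAB description TAB genes."""
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, genes")
        name, _desc, *genes = fields
        genes = [g for g in genes if g]
        sets.append(GeneSet(name=name, genes=tuple(genes)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: PathLike, description: str = "na") -> None:
    lines = ["\t".join([gs.name, description, *gs.genes]) for gs in sets]
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression_tsv(path: PathLike) -> pd.DataFrame:
    """Gene-by-sample TSV: first column gene ids, header row sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_expression_tsv(expr: pd.DataFrame, path: PathLike) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_scores_tsv(path: PathLike, column: str | None = None) -> pd.Series:
    """Two-column (sample_id, score) TSV, or a wider matrix with ``column`` named."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if column is None:
        if df.shape[1] != 1:
            raise ValueError(
                f"{path} has {df.shape[1]} score columns; pass column= to choose one"
            )
        column = df.columns[0]
    return df[column].astype(float)


def write_scores_tsv(scores: pd.Series, path: PathLike, name: str = "score") -> None:
    frame = scores.rename(name).to_frame()
    frame.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")


def write_groups_tsv(cohort: StratifiedCohort, path: PathLike) -> None:
    cohort.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_groups_tsv(path: PathLike) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError(f"{path} lacks sample_id/group columns")
    return pd.Series(df["group"].to_numpy(), index=df["sample_id"].astype(str), name="group")


def read_mtx_dir(path: PathLike) -> SingleCellMatrix:
    """MatrixMarket triplet directory: matrix.mtx + genes.tsv + barcodes.tsv.

    An optional single-column ``cycling.tsv`` (0/1 per cell) restores the
    cell-cycle flag.
    """
    path = Path(path)
    counts = sparse.csc_matrix(spio.mmread(path / "matrix.mtx"))
    genes = (path / "genes.tsv").read_text().split()
    barcodes = (path / "barcodes.tsv").read_text().split()
    cycling = None
    cyc_path = path / "cycling.tsv"
    if cyc_path.exists():
        cycling = np.array([bool(int(v)) for v in cyc_path.read_text().split()])
    return SingleCellMatrix(gene_ids=genes, cell_ids=barcodes, counts=counts, cycling=cycling)


def write_mtx_dir(sc: SingleCellMatrix, path: PathLike) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    counts = sc.counts
    if not sparse.issparse(counts):
        counts = sparse.coo_matrix(counts)
    spio.mmwrite(str(path / "matrix.mtx"), counts, field="integer")
    (path / "genes.tsv").write_text("\n".join(sc.gene_ids) + "\n")
    (path / "barcodes.tsv").write_text("\n".join(sc.cell_ids) + "\n")
    if sc.cycling is not None:
        (path / "cycling.tsv").write_text(
            "\n".join(str(int(v)) for v in sc.cycling) + "\n"
        )
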