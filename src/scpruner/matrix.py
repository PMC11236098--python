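"""Count-matrix I/O, quality control, library-size normalization and gene alignment.

Counts are held dense (cells x genes, non-negative integers).  Normalization
divides each cell by its total count, rescales by the median library size
across cells and applies log1p, the standard median-ratio transform for
scRNA-seq expression.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .exceptions import (
    DegenerateDataError,
    FormatError,
    IncompatibleDataError,
    ValidationError,
)

#: Reserved output label for rejected (novel) cells; never a valid input class.
UNKNOWN_LABEL = "unknown"


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{what} are not unique")


@dataclass
class CountMatrix:
    """Raw counts for ``n`` cells by ``m`` genes."""

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValidationError("counts shape inconsistent with cell/gene ids")
        if np.issubdtype(self.counts.dtype, np.floating):
            if not np.all(np.isfinite(self.counts)):
                raise ValidationError("counts contain non-finite entries")
            if np.any(self.counts != np.round(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.gene_ids, "gene ids")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class NormalizedMatrix:
    """log1p(median-scaled counts); values are non-negative reals."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    library_median: float

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, indices: np.ndarray) -> "NormalizedMatrix":
        idx = np.asarray(indices, dtype=np.intp)
        return NormalizedMatrix(
            values=self.values[:, idx],
            cell_ids=list(self.cell_ids),
            gene_ids=[self.gene_ids[i] for i in idx],
            library_median=self.library_median,
        )


@dataclass
class LabelVector:
    """Per-cell labels plus the ordered (sorted) category universe."""

    labels: np.ndarray
    categories: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if not self.categories:
            self.categories = sorted(set(self.labels.tolist()))
        missing = set(self.labels.tolist()) - set(self.categories)
        if missing:
            raise ValidationError(f"labels outside categories: {sorted(missing)}")

    @property
    def n_classes(self) -> int:
        return len(self.categories)

    def codes(self) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.categories)}
        return np.fromiter((lut[v] for v in self.labels), dtype=np.int64,
                           count=len(self.labels))


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path: str | os.PathLike, fmt: str = "csv") -> CountMatrix:
    """Read a counts file into cells x genes orientation.

    ``csv``: dense matrix, first row gene ids, first column cell ids.
    ``mtx10x``: Matrix Market triplet stored genes x cells (10x convention)
    with sibling ``features.tsv`` / ``barcodes.tsv`` files; *path* may be the
    ``.mtx`` file or its directory.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if fmt == "csv":
        try:
            df = pd.read_csv(path, index_col=0)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise FormatError(f"malformed CSV {path}: {exc}") from exc
        if df.shape[1] == 0:
            raise FormatError(f"CSV {path} has no gene columns")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError(f"CSV {path} contains non-numeric entries")
        return CountMatrix(values, [str(c) for c in df.index],
                           [str(g) for g in df.columns])
    if fmt == "mtx10x":
        if path.is_dir():
            mtx_path = path / "matrix.mtx"
        else:
            mtx_path = path
        folder = mtx_path.parent
        features = folder / "features.tsv"
        if not features.exists():
            features = folder / "genes.tsv"
        barcodes = folder / "barcodes.tsv"
        for f in (mtx_path, features, barcodes):
            if not f.exists():
                raise FormatError(f"missing mtx10x companion file: {f}")
        try:
            mat = spio.mmread(mtx_path)
        except Exception as exc:
            raise FormatError(f"malformed Matrix Market header in {mtx_path}: {exc}") from exc
        if sparse.issparse(mat):
            mat = mat.toarray()
        gene_ids = pd.read_csv(features, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
        cell_ids = pd.read_csv(barcodes, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
        # on disk: genes x cells -> transpose to cells x genes
        return CountMatrix(np.asarray(mat).T, cell_ids, gene_ids)
    raise FormatError(f"unknown counts format: {fmt!r}")


def read_labels(path: str | os.PathLike) -> pd.Series:
    """Read a two-column (cell_id, label) TSV with header into a Series."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"label file {path} needs two columns (cell_id, label)")
    series = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)
    if (series == UNKNOWN_LABEL).any():
        raise ValidationError(
            f"'{UNKNOWN_LABEL}' is a reserved output label and may not appear "
            "as an input class"
        )
    return series


def labels_for(cm: CountMatrix | NormalizedMatrix, series: pd.Series) -> LabelVector:
    """Order a label Series to the matrix's cells."""
    missing = [c for c in cm.cell_ids if c not in series.index]
    if missing:
        raise ValidationError(f"{len(missing)} cells lack labels (e.g. {missing[0]!r})")
    return LabelVector(np.asarray(series.loc[cm.cell_ids].values, dtype=object))


def write_counts_csv(cm: CountMatrix, path: str | os.PathLike) -> None:
    pd.DataFrame(cm.counts, index=cm.cell_ids, columns=cm.gene_ids).to_csv(path)


def write_counts_mtx10x(cm: CountMatrix, folder: str | os.PathLike) -> None:
    """Write matrix.mtx (genes x cells) + features.tsv + barcodes.tsv."""
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(folder / "matrix.mtx", sparse.coo_matrix(cm.counts.T))
    (folder / "features.tsv").write_text("".join(f"{g}\t{g}\n" for g in cm.gene_ids))
    (folder / "barcodes.tsv").write_text("".join(f"{c}\n" for c in cm.cell_ids))


def write_labels_tsv(cell_ids: Sequence[str], labels: Sequence[str],
                     path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("cell_id\tlabel\n")
        for c, l in zip(cell_ids, labels):
            fh.write(f"{c}\t{l}\n")


# ---------------------------------------------------------------------------
# QC / normalization / alignment


def qc_filter(cm: CountMatrix, min_cells_per_gene: int = 3,
              min_genes_per_cell: int = 200) -> CountMatrix:
    """Drop sparsely detected genes, then sparsely covered cells, in that order."""
    if min_cells_per_gene < 0 or min_genes_per_cell < 0:
        raise ValidationError("QC thresholds must be non-negative")
    detected = cm.counts > 0
    gene_keep = detected.sum(axis=0) >= min_cells_per_gene
    counts = cm.counts[:, gene_keep]
    cell_keep = (counts > 0).sum(axis=1) >= min_genes_per_cell
    counts = counts[cell_keep]
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise DegenerateDataError(
            f"QC left an empty matrix (thresholds {min_cells_per_gene}, "
            f"{min_genes_per_cell})"
        )
    return CountMatrix(
        counts,
        [c for c, k in zip(cm.cell_ids, cell_keep) if k],
        [g for g, k in zip(cm.gene_ids, gene_keep) if k],
    )


def normalize(cm: CountMatrix) -> NormalizedMatrix:
    """Median-library-size scaling followed by log1p.

    values[i, j] = ln(1 + counts[i, j] / libsize_i * median(libsize)).
    """
    libsize = cm.counts.sum(axis=1)
    if np.any(libsize == 0):
        raise DegenerateDataError(
            "cells with zero total counts present; run qc_filter first"
        )
    median = float(np.median(libsize))
    values = np.log1p(cm.counts / libsize[:, None] * median)
    return NormalizedMatrix(values, list(cm.cell_ids), list(cm.gene_ids), median)


def align_genes(ref: NormalizedMatrix,
                query: NormalizedMatrix) -> tuple[NormalizedMatrix, NormalizedMatrix]:
    """Restrict both matrices to their shared genes, in the reference's order."""
    query_set = set(query.gene_ids)
    shared = [g for g in ref.gene_ids if g in query_set]
    if not shared:
        raise IncompatibleDataError("reference and query share no genes")
    ref_idx = [ref.gene_ids.index(g) for g in shared] if len(shared) < ref.n_genes \
        else list(range(ref.n_genes))
    qlut = {g: i for i, g in enumerate(query.gene_ids)}
    query_idx = [qlut[g] for g in shared]
    return ref.subset_genes(np.asarray(ref_idx)), query.subset_genes(np.asarray(query_idx))
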