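"""Expression-matrix input/output, gene filtering, and row standardization.

The canonical in-memory container is :class:`ExpressionMatrix`: a dense
gene x sample matrix with unique row and column identifiers.  All
downstream pair statistics assume rows standardized to mean 0 and
standard deviation 1 (population divisor, so that each row satisfies
``sum(g**2) == N`` exactly and ``g_i @ g_j / N`` is the Pearson
correlation).

Loaders accept dense TSV/CSV (first column gene ids, header row sample
ids) and the MatrixMarket coordinate triplet layout common in
single-cell data (an ``.mtx`` file plus one-id-per-line row-name and
column-name sidecar files).  Matrices with missing values are rejected:
the pipeline consumes complete, already-normalized matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "filter_zero_fraction",
    "standardize",
    "prepare",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Dense gene x sample expression matrix with identifiers.

    Parameters
    ----------
    values
        Real matrix of shape ``(p, N)``: p genes in rows, N samples in
        columns.
    gene_ids
        Unique gene identifiers, length p.
    sample_ids
        Unique sample identifiers, length N.
    standardized
        True if every row has mean 0 and (population) standard
        deviation 1.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    standardized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(map(str, self.gene_ids)))
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        if values.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got shape {values.shape}")
        p, n = values.shape
        if len(self.gene_ids) != p:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {p} rows"
            )
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} columns"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(values)):
            rows, cols = np.where(~np.isfinite(values))
            loc = ", ".join(
                f"({self.gene_ids[r]}, {self.sample_ids[c]})"
                for r, c in list(zip(rows, cols))[:5]
            )
            raise ValueError(f"matrix contains missing/non-finite values at {loc}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    def subset_genes(self, row_indices: np.ndarray) -> "ExpressionMatrix":
        """Return a copy restricted to the given gene rows (order kept)."""
        idx = np.asarray(row_indices, dtype=int)
        return ExpressionMatrix(
            self.values[idx],
            tuple(self.gene_ids[i] for i in idx),
            self.sample_ids,
            standardized=self.standardized,
        )


def _check_unique(ids: tuple[str, ...], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValueError(f"duplicate {what} ids: {', '.join(sorted(dups))}")


def read_expression(
    path: str | Path,
    format: str | None = None,
    *,
    samples_in_rows: bool = False,
    row_names: str | Path | None = None,
    col_names: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV, CSV, or an MTX triplet.

    Parameters
    ----------
    path
        Matrix file.  For ``mtx-triplet`` this is the ``.mtx``
        coordinate file and `row_names` / `col_names` point to
        one-id-per-line sidecar files (default: ``<stem>.rows.txt`` /
        ``<stem>.cols.txt`` next to the matrix).
    format
        One of ``tsv``, ``csv``, ``mtx-triplet``; inferred from the
        file suffix when omitted.
    samples_in_rows
        If True the file is transposed after loading (single-cell
        matrices commonly come cells-in-rows); ids are swapped
        accordingly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        suffix = path.suffix.lower()
        format = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".mtx": "mtx-triplet"}.get(
            suffix
        )
        if format is None:
            raise ValueError(f"cannot infer format from suffix {suffix!r}")

    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"NA value at row {df.index[r]!r}, column {df.columns[c]!r}"
            )
        gene_ids = tuple(map(str, df.index))
        sample_ids = tuple(map(str, df.columns))
    elif format == "mtx-triplet":
        rows_path = Path(row_names) if row_names else path.with_suffix("").with_suffix(".rows.txt")
        cols_path = Path(col_names) if col_names else path.with_suffix("").with_suffix(".cols.txt")
        for p in (rows_path, cols_path):
            if not p.exists():
                raise FileNotFoundError(f"sidecar name file missing: {p}")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        values = np.asarray(mat, dtype=float)
        gene_ids = tuple(rows_path.read_text().split())
        sample_ids = tuple(cols_path.read_text().split())
    else:
        raise ValueError(f"unknown format {format!r}")

    if samples_in_rows:
        values = values.T
        gene_ids, sample_ids = sample_ids, gene_ids
    return ExpressionMatrix(values, gene_ids, sample_ids, standardized=False)


def write_expression(X: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write a matrix as TSV/CSV (first column gene ids, header samples)."""
    sep = {"tsv": "\t", "csv": ","}[format]
    X.to_frame().to_csv(Path(path), sep=sep)


def filter_zero_fraction(X: ExpressionMatrix, max_zero_frac: float) -> ExpressionMatrix:
    """Drop genes whose fraction of exactly-zero entries exceeds the cap.

    Mirrors the usual sparse-data preprocessing step (e.g. removing
    genes with >25% zero counts in single-cell data).  Keeps genes with
    zero fraction ``<= max_zero_frac``, preserving order.
    """
    if not 0.0 <= max_zero_frac <= 1.0:
        raise ValueError("max_zero_frac must be in [0, 1]")
    if X.standardized:
        raise ValueError("filter by zero fraction before standardizing")
    frac = (X.values == 0).mean(axis=1)
    keep = np.nonzero(frac <= max_zero_frac)[0]
    if keep.size == 0:
        raise ValueError(
            f"all {X.n_genes} genes exceed zero fraction {max_zero_frac}; "
            "use a looser threshold"
        )
    if keep.size < X.n_genes:
        logger.info(
            "zero-fraction filter: kept %d of %d genes (threshold %.3g)",
            keep.size, X.n_genes, max_zero_frac,
        )
    return X.subset_genes(keep)


def standardize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene row to mean 0, standard deviation 1.

    The population divisor (n) is used, so each standardized row g
    satisfies ``sum(g**2) == N`` and ``g_i @ g_j / N`` is the Pearson
    correlation of the pair.  Rows with zero variance are an error:
    filter or use :func:`prepare` first.
    """
    mean = X.values.mean(axis=1, keepdims=True)
    sd = X.values.std(axis=1, ddof=0, keepdims=True)
    bad = np.nonzero(sd.ravel() == 0)[0]
    if bad.size:
        names = ", ".join(X.gene_ids[i] for i in bad[:10])
        raise ValueError(f"constant gene rows cannot be standardized: {names}")
    return ExpressionMatrix(
        (X.values - mean) / sd, X.gene_ids, X.sample_ids, standardized=True
    )


def prepare(
    X: ExpressionMatrix,
    max_zero_frac: float = 1.0,
    log1p: bool = False,
) -> ExpressionMatrix:
    """Forgiving pipeline entry: filter, drop constants, standardize.

    Chains the zero-fraction filter, an optional log(1+x) transform,
    a logged drop of constant genes, and standardization.  The core
    operations stay strict; this wrapper is for interactive use and
    the CLI.
    """
    X = filter_zero_fraction(X, max_zero_frac)
    if log1p:
        X = ExpressionMatrix(
            np.log1p(X.values), X.gene_ids, X.sample_ids, standardized=False
        )
    sd = X.values.std(axis=1, ddof=0)
    keep = np.nonzero(sd > 0)[0]
    if keep.size < X.n_genes:
        dropped = [X.gene_ids[i] for i in range(X.n_genes) if sd[i] == 0]
        logger.warning("dropping %d constant genes: %s", len(dropped),
                       ", ".join(dropped[:10]))
        if keep.size == 0:
            raise ValueError("no non-constant genes remain")
        X = X.subset_genes(keep)
    return standardize(X)
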