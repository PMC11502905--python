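"""Readers and writers for the on-disk formats.

Counts travel as a CellRanger-style Matrix-Market triplet
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``) or as dense
delimited text with gene rows and a header row of cell ids. Annotation,
ligand-receptor pair and ortholog tables are plain delimited text.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import (
    DEFAULT_CELL_TYPES,
    DEFAULT_TIME_POINTS,
    CellAnnotation,
    CountMatrix,
    LRPairTable,
    OrthologMap,
)
from .errors import FormatError, ValidationError


def _read_ids(path: str) -> list[str]:
    """One identifier per line; extra tab-separated columns are ignored."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_counts_mtx(matrix_path: str, features_path: str, barcodes_path: str) -> CountMatrix:
    """Read a Matrix-Market coordinate triplet into a :class:`CountMatrix`.

    The matrix file must declare the ``integer`` field: UMI counts are
    integers by definition, so ``real``-valued files are rejected rather
    than silently truncated. Coordinates absent from the file are zero.
    """
    try:
        rows, cols, _entries, fmt, field, _sym = scipy.io.mminfo(matrix_path)
    except ValueError as exc:
        raise FormatError(f"{matrix_path}: not a Matrix-Market file ({exc})") from exc
    if field != "integer":
        raise FormatError(
            f"{matrix_path}: Matrix-Market field is '{field}', expected 'integer' "
            "(UMI counts)"
        )
    mat = scipy.io.mmread(matrix_path)
    values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    values = values.astype(np.int64)
    genes = _read_ids(features_path)
    cells = _read_ids(barcodes_path)
    if len(genes) != rows:
        raise FormatError(
            f"{features_path}: {len(genes)} feature ids for {rows} matrix rows"
        )
    if len(cells) != cols:
        raise FormatError(
            f"{barcodes_path}: {len(cells)} barcodes for {cols} matrix columns"
        )
    if values.size and values.min() < 0:
        raise ValidationError(f"{matrix_path}: negative counts")
    return CountMatrix(values, genes, cells)


def write_counts_mtx(counts: CountMatrix, out_dir: str) -> dict:
    """Write ``matrix.mtx``/``features.tsv``/``barcodes.tsv`` into ``out_dir``.

    Returns the mapping of file roles to paths. Round-trips exactly through
    :func:`read_counts_mtx` (values and identifier order preserved).
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "matrix": os.path.join(out_dir, "matrix.mtx"),
        "features": os.path.join(out_dir, "features.tsv"),
        "barcodes": os.path.join(out_dir, "barcodes.tsv"),
    }
    coo = scipy.sparse.coo_matrix(counts.values)
    if coo.nnz:
        scipy.io.mmwrite(paths["matrix"], coo, field="integer")
    else:  # mmwrite defaults an empty coordinate list to the 'real' field
        with open(paths["matrix"], "w") as fh:
            fh.write("%%MatrixMarket matrix coordinate integer general\n")
            fh.write(f"{counts.n_genes} {counts.n_cells} 0\n")
    with open(paths["features"], "w") as fh:
        fh.write("".join(g + "\n" for g in counts.gene_ids))
    with open(paths["barcodes"], "w") as fh:
        fh.write("".join(c + "\n" for c in counts.cell_ids))
    return paths


def _sep_for(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.endswith(".csv") else "\t"


def read_counts_dense(path: str, sep: str | None = None) -> CountMatrix:
    """Dense delimited counts: gene rows, first column gene ids, header of cell ids."""
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if np.issubdtype(values.dtype, np.floating) and np.all(values == np.floor(values)):
            values = values.astype(np.int64)
        else:
            raise ValidationError(f"{path}: non-integer entries in dense count table")
    return CountMatrix(values, [str(g) for g in df.index], [str(c) for c in df.columns])


def read_annotation(
    path: str,
    cell_types: tuple[str, ...] | None = DEFAULT_CELL_TYPES,
    time_points: tuple[str, ...] = DEFAULT_TIME_POINTS,
    sep: str | None = None,
) -> CellAnnotation:
    """Read a per-cell annotation table (columns cell_id, cell_type, time_point)."""
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str)
    required = {"cell_id", "cell_type", "time_point"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: header must contain {sorted(required)}")
    if df["cell_id"].duplicated().any():
        dupes = sorted(df.loc[df["cell_id"].duplicated(), "cell_id"].unique())
        raise ValidationError(f"{path}: duplicate cell_id {dupes[:5]}")
    df = df.set_index("cell_id")
    return CellAnnotation(df, cell_types=cell_types, time_points=time_points)


def write_annotation(ann: CellAnnotation, path: str) -> None:
    ann.table.rename_axis("cell_id").to_csv(path, sep="\t")


def read_lr_pairs(path: str, sep: str | None = None) -> LRPairTable:
    """Read a ligand-receptor pair table (header ligand,receptor[,pathway])."""
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str)
    if not {"ligand", "receptor"}.issubset(df.columns):
        raise FormatError(f"{path}: header must contain ligand and receptor")
    return LRPairTable(df)


def write_lr_pairs(pairs: LRPairTable, path: str) -> None:
    pairs.table.to_csv(path, sep="\t", index=False)


def read_ortholog_map(path: str, sep: str | None = None) -> OrthologMap:
    """Read a precomputed source-to-target symbol mapping (header source,target)."""
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str)
    if not {"source", "target"}.issubset(df.columns):
        raise FormatError(f"{path}: header must contain source and target")
    return OrthologMap(df)
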