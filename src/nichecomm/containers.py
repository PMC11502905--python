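"""Core typed containers for plate-based single-cell UMI analysis.

The central objects are a genes x cells integer :class:`CountMatrix`, a
per-cell :class:`CellAnnotation` carrying the (cell_type, time_point) labels
that the permutation null shuffles, a curated :class:`LRPairTable` of
ligand-receptor gene pairs, and an :class:`OrthologMap` for translating the
pair table between species (e.g. human reference pairs to mouse symbols).

Gene symbols are matched case-sensitively throughout: mouse/human symbol
case is semantically meaningful (``Apoe`` is a mouse gene, ``APOE`` its
human ortholog).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Ordered time-point vocabulary of the photothrombosis stroke design:
#: uninjured controls, day 1 and day 7 after injury.
DEFAULT_TIME_POINTS: tuple[str, ...] = ("uninjured", "PT_D1", "PT_D7")

#: The two sorted populations of the study design.
DEFAULT_CELL_TYPES: tuple[str, ...] = ("microglia", "NSPC")


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Series(ids)
        dupes = sorted(dupes[dupes.duplicated()].unique())
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class CountMatrix:
    """Genes x cells matrix of non-negative integer UMI counts.

    Parameters
    ----------
    values
        2-D integer array, rows are genes, columns are cells.
    gene_ids
        Gene symbols in row order (unique).
    cell_ids
        Cell barcodes/identifiers in column order (unique).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValidationError("count matrix must be 2-D (genes x cells)")
        if not np.issubdtype(self.values.dtype, np.integer):
            if np.issubdtype(self.values.dtype, np.floating) and np.all(
                self.values == np.floor(self.values)
            ):
                self.values = self.values.astype(np.int64)
            else:
                raise ValidationError("UMI counts must be integers")
        if self.values.size and self.values.min() < 0:
            raise ValidationError("UMI counts must be non-negative")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[0]} rows"
            )
        if len(self.cell_ids) != self.values.shape[1]:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {self.values.shape[1]} columns"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.cell_ids, "cell ids")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Total UMIs per cell (column sums)."""
        return np.asarray(self.values.sum(axis=0)).ravel()

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        """Return a new matrix keeping the cells where ``mask`` is true, in order."""
        mask = np.asarray(mask, dtype=bool)
        kept = [c for c, m in zip(self.cell_ids, mask) if m]
        return CountMatrix(self.values[:, mask], list(self.gene_ids), kept)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class CellAnnotation:
    """Per-cell ``(cell_type, time_point)`` labels with declared vocabularies.

    ``table`` is indexed by cell_id with columns ``cell_type`` and
    ``time_point``; lookups are order-independent. These are exactly the
    labels that the ligand-receptor permutation null shuffles.
    """

    table: pd.DataFrame
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    time_points: tuple[str, ...] = DEFAULT_TIME_POINTS

    def __post_init__(self) -> None:
        t = self.table
        if not {"cell_type", "time_point"}.issubset(t.columns):
            raise ValidationError("annotation needs cell_type and time_point columns")
        _check_unique(list(t.index), "cell ids in annotation")
        for col, vocab in (("cell_type", self.cell_types), ("time_point", self.time_points)):
            vals = t[col].astype(str)
            if (vals.str.len() == 0).any() or vals.isin(["nan", "None"]).any():
                raise ValidationError(f"empty {col} label")
            if vocab is not None:
                bad = sorted(set(vals) - set(vocab))
                if bad:
                    raise ValidationError(
                        f"{col} label(s) {bad} outside vocabulary {list(vocab)}"
                    )
        self.table = t[["cell_type", "time_point"]].astype(str)

    @property
    def n_cells(self) -> int:
        return len(self.table)

    def align(self, cell_ids: list[str]) -> pd.DataFrame:
        """Labels for ``cell_ids`` in that order.

        Cells annotated but absent from ``cell_ids`` are ignored with a
        warning; cells lacking an annotation are an error (every analyzed
        cell needs labels).
        """
        missing = [c for c in cell_ids if c not in self.table.index]
        if missing:
            raise ValidationError(
                f"{len(missing)} cell(s) lack annotation, e.g. {missing[:5]}"
            )
        extra = len(self.table) - len(cell_ids)
        if extra > 0:
            logger.warning("%d annotated cell(s) absent from the matrix; ignored", extra)
        return self.table.loc[cell_ids]

    def joint_labels(self, cell_ids: list[str]) -> pd.Series:
        """``"cell_type|time_point"`` joint label per cell, aligned to ``cell_ids``."""
        t = self.align(cell_ids)
        return t["cell_type"].str.cat(t["time_point"], sep="|")


@dataclass
class LRPairTable:
    """Curated ligand-receptor gene pairs, optionally tagged by pathway."""

    table: pd.DataFrame  # columns: ligand, receptor [, pathway]

    def __post_init__(self) -> None:
        t = self.table
        if not {"ligand", "receptor"}.issubset(t.columns):
            raise ValidationError("pair table needs ligand and receptor columns")
        cols = ["ligand", "receptor"] + (["pathway"] if "pathway" in t.columns else [])
        t = t[cols].astype(str).reset_index(drop=True)
        for col in ("ligand", "receptor"):
            if (t[col].str.len() == 0).any() or t[col].isin(["nan"]).any():
                raise ValidationError(f"empty {col} symbol in pair table")
        if t.duplicated(["ligand", "receptor"]).any():
            raise ValidationError("duplicate (ligand, receptor) pairs")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.table["ligand"], self.table["receptor"]))


@dataclass
class OrthologMap:
    """Source-to-target gene symbol mapping (possibly one-to-many)."""

    table: pd.DataFrame  # columns: source, target
    _index: dict = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        t = self.table
        if not {"source", "target"}.issubset(t.columns):
            raise ValidationError("ortholog map needs source and target columns")
        t = t[["source", "target"]].astype(str).drop_duplicates().reset_index(drop=True)
        for col in ("source", "target"):
            if (t[col].str.len() == 0).any() or t[col].isin(["nan"]).any():
                raise ValidationError(f"empty {col} symbol in ortholog map")
        if t.empty:
            raise ValidationError("ortholog map is empty")
        self.table = t
        self._index = {
            src: list(grp["target"]) for src, grp in t.groupby("source", sort=False)
        }

    def targets(self, source_symbol: str) -> list[str]:
        """Mapped target symbols for ``source_symbol`` (empty list if unmapped)."""
        return list(self._index.get(source_symbol, []))
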