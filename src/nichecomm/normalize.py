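"""Library-size log-normalization and per-group mean expression.

Counts are scaled to a common library size and log-transformed:

    value(g, c) = ln(1 + count(g, c) / library(c) * scale_factor)

with ``scale_factor = 10000`` by default (the standard single-cell
LogNormalize convention). Group means — the arithmetic mean of the
log-normalized expression over all cells sharing a
``(cell_type, time_point)`` label, zeros included — are the sole input to
the ligand-receptor interaction score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CellAnnotation, CountMatrix
from .errors import ParameterError

logger = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """Genes x cells matrix of log-normalized expression values.

    For every cell with a nonzero library, the back-transformed values
    satisfy ``sum_g(exp(value) - 1) == scale_factor`` (natural-log case).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    scale_factor: float

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def log_normalize(
    counts: CountMatrix, scale_factor: float = 10_000.0, base: float | None = None
) -> NormalizedMatrix:
    """Scale each cell to ``scale_factor`` total counts and apply log1p.

    ``base=None`` uses the natural logarithm (the convention the group
    means and fold changes assume); any other base divides through by
    ``ln(base)``. Zero-library cells map to all-zero columns with a logged
    warning.
    """
    if scale_factor <= 0:
        raise ParameterError("scale_factor must be positive")
    lib = counts.library_sizes().astype(float)
    zero = lib == 0
    if zero.any():
        logger.warning("%d zero-library cell(s) normalized to all-zero columns", zero.sum())
    safe_lib = np.where(zero, 1.0, lib)
    values = np.log1p(counts.values / safe_lib * scale_factor)
    if base is not None:
        values = values / math.log(base)
    values[:, zero] = 0.0
    return NormalizedMatrix(values, list(counts.gene_ids), list(counts.cell_ids), scale_factor)


@dataclass
class GroupMeans:
    """Mean log-normalized expression per (cell_type, time_point, gene).

    ``means`` is a genes x groups DataFrame whose columns are a
    ``(cell_type, time_point)`` MultiIndex; ``group_sizes`` holds the cell
    count per group (every stored group has >= 1 cell).
    """

    means: pd.DataFrame
    group_sizes: pd.Series

    def get(self, cell_type: str, time_point: str, gene: str) -> float:
        """Mean for one (group, gene); raises ``KeyError`` naming a missing group."""
        key = (cell_type, time_point)
        if key not in self.means.columns:
            raise KeyError(f"no cells in group (cell_type={cell_type!r}, time_point={time_point!r})")
        if gene not in self.means.index:
            raise KeyError(f"gene {gene!r} not in the gene universe")
        return float(self.means.at[gene, key])

    def groups(self) -> list[tuple[str, str]]:
        return list(self.means.columns)

    def to_long(self) -> pd.DataFrame:
        """Long-format table (cell_type, time_point, gene, mean, n_cells)."""
        long = self.means.T.stack().rename("mean").reset_index()
        long.columns = ["cell_type", "time_point", "gene", "mean"]
        sizes = self.group_sizes
        long["n_cells"] = [
            int(sizes[(ct, tp)]) for ct, tp in zip(long["cell_type"], long["time_point"])
        ]
        return long


def group_means(norm: NormalizedMatrix, ann: CellAnnotation) -> GroupMeans:
    """Average the log-normalized expression over each observed joint group.

    Means run over *all* cells of a group, including those with zero
    expression. Only groups with at least one cell appear.
    """
    labels = ann.align(norm.cell_ids)
    joint = pd.Series(list(zip(labels["cell_type"], labels["time_point"])))
    codes, uniques = pd.factorize(joint, sort=True)
    n_groups = len(uniques)
    sums = np.zeros((norm.n_genes, n_groups))
    sizes = np.zeros(n_groups, dtype=int)
    for g in range(n_groups):
        mask = codes == g
        sizes[g] = mask.sum()
        sums[:, g] = norm.values[:, mask].sum(axis=1)
    means = sums / sizes
    cols = pd.MultiIndex.from_tuples(list(uniques), names=["cell_type", "time_point"])
    return GroupMeans(
        means=pd.DataFrame(means, index=pd.Index(norm.gene_ids, name="gene"), columns=cols),
        group_sizes=pd.Series(sizes, index=cols, name="n_cells"),
    )
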