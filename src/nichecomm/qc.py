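"""Three-rule cell quality control for plate-based UMI data.

Cells are screened, in order, by

1. a **doublet rule** — total UMIs more than ``mad_k`` median absolute
   deviations above the median library size flag a putative doublet
   (sorter wells occasionally receive two cells, roughly doubling the
   library);
2. a **UMI floor** — cells need at least ``min_umi`` total counts to carry
   signal;
3. a **mitochondrial ceiling** — cells with more than ``max_mito_pct`` %
   of their library on mitochondrial genes (symbols starting ``mt-``) are
   dying or lysed and are discarded.

The MAD is unscaled (median of absolute deviations from the median, no
1.4826 normal-consistency factor); an optional ``mad_scale`` restores the
factor for callers who want it. The doublet rule is one-sided: only the
high tail of the library-size distribution is suspect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .errors import EmptyAfterQCError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class QCParams:
    """Thresholds of the three QC rules.

    mad_k
        Doublet cut in MADs above the median library size.
    min_umi
        Library-size floor; cells with fewer total UMIs are discarded.
        Inclusive by default (a cell at exactly ``min_umi`` is retained);
        set ``umi_strict`` to require strictly more.
    max_mito_pct
        Maximum tolerated percentage of the library on mitochondrial genes.
    mito_prefix
        Gene-symbol prefix identifying mitochondrial genes; matched
        case-insensitively unless ``mito_case_sensitive``.
    mad_scale
        Multiplier applied to the raw MAD (1.0 = unscaled; 1.4826 gives the
        normal-consistent estimator).
    """

    mad_k: float = 3.0
    min_umi: int = 1000
    max_mito_pct: float = 25.0
    mito_prefix: str = "mt-"
    mad_scale: float = 1.0
    umi_strict: bool = False
    mito_case_sensitive: bool = False

    def __post_init__(self) -> None:
        if self.mad_k <= 0 or self.min_umi <= 0 or self.mad_scale <= 0:
            raise ParameterError("QC thresholds must be strictly positive")
        if not (0 < self.max_mito_pct <= 100):
            raise ParameterError("max_mito_pct must lie in (0, 100]")


@dataclass
class QCReport:
    """Per-cell fates and removal counts for one :func:`apply_qc` call.

    ``ledger`` is indexed by cell_id with columns ``library_size``,
    ``mito_pct`` and ``fate`` (one of ``retained``, ``doublet``,
    ``low_umi``, ``high_mito``); each removed cell is attributed to the
    first rule that removed it.
    """

    n_input: int
    n_doublet_removed: int
    n_low_umi_removed: int
    n_high_mito_removed: int
    n_retained: int
    ledger: pd.DataFrame

    def __post_init__(self) -> None:
        removed = self.n_doublet_removed + self.n_low_umi_removed + self.n_high_mito_removed
        if self.n_input != self.n_retained + removed:
            raise ValueError("QC report does not conserve cells")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_doublet_removed": self.n_doublet_removed,
            "n_low_umi_removed": self.n_low_umi_removed,
            "n_high_mito_removed": self.n_high_mito_removed,
            "n_retained": self.n_retained,
            "cells": {
                cid: {
                    "library_size": int(row.library_size),
                    "mito_pct": float(row.mito_pct),
                    "fate": row.fate,
                }
                for cid, row in self.ledger.iterrows()
            },
        }


def library_sizes(counts: CountMatrix) -> np.ndarray:
    """Total UMIs per cell."""
    return counts.library_sizes()


def mad_doublet_mask(totals: np.ndarray, k: float = 3.0, scale: float = 1.0) -> np.ndarray:
    """True where ``total > median + k * MAD`` (upper tail only).

    MAD is the median of absolute deviations from the median, multiplied by
    ``scale`` (default unscaled). If the MAD is zero the rule degenerates to
    ``total > median``.
    """
    totals = np.asarray(totals, dtype=float)
    if totals.size == 0:
        raise ParameterError("cannot compute MAD of an empty vector")
    med = np.median(totals)
    mad = np.median(np.abs(totals - med)) * scale
    return totals > med + k * mad


def mito_percentages(
    counts: CountMatrix, prefix: str = "mt-", case_sensitive: bool = False
) -> np.ndarray:
    """Percentage of each cell's library on genes whose symbol starts with ``prefix``.

    Zero-library cells are defined to have 0%. If no gene matches the
    prefix a warning is logged and all percentages are zero.
    """
    if case_sensitive:
        is_mito = np.array([g.startswith(prefix) for g in counts.gene_ids])
    else:
        p = prefix.lower()
        is_mito = np.array([g.lower().startswith(p) for g in counts.gene_ids])
    if not is_mito.any():
        logger.warning("no gene symbol matches mitochondrial prefix %r", prefix)
        return np.zeros(counts.n_cells)
    lib = counts.library_sizes().astype(float)
    mito = counts.values[is_mito].sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(lib > 0, 100.0 * mito / lib, 0.0)
    return pct


def apply_qc(counts: CountMatrix, params: QCParams | None = None) -> tuple[CountMatrix, QCReport]:
    """Apply the three QC rules in order and return the filtered matrix plus report.

    The doublet mask is computed on the full input population; the UMI
    floor and mitochondrial ceiling are then applied to the survivors.
    Surviving cells keep their original order. Raises
    :class:`~nichecomm.errors.EmptyAfterQCError` if nothing survives.
    """
    if params is None:
        params = QCParams()
    lib = counts.library_sizes()
    mito_pct = mito_percentages(
        counts, params.mito_prefix, case_sensitive=params.mito_case_sensitive
    )
    fate = np.full(counts.n_cells, "retained", dtype=object)

    doublet = mad_doublet_mask(lib, params.mad_k, params.mad_scale)
    fate[doublet] = "doublet"

    if params.umi_strict:
        low = (lib <= params.min_umi) & (fate == "retained")
    else:
        low = (lib < params.min_umi) & (fate == "retained")
    fate[low] = "low_umi"

    high = (mito_pct > params.max_mito_pct) & (fate == "retained")
    fate[high] = "high_mito"

    keep = fate == "retained"
    if not keep.any():
        raise EmptyAfterQCError("no cell survives quality control")

    ledger = pd.DataFrame(
        {"library_size": lib, "mito_pct": mito_pct, "fate": fate},
        index=pd.Index(counts.cell_ids, name="cell_id"),
    )
    report = QCReport(
        n_input=counts.n_cells,
        n_doublet_removed=int(doublet.sum()),
        n_low_umi_removed=int(low.sum()),
        n_high_mito_removed=int(high.sum()),
        n_retained=int(keep.sum()),
        ledger=ledger,
    )
    return counts.subset_cells(keep), report
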