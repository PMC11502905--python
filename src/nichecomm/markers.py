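"""Marker-gene detection and gene-signature overlap.

Differential expression between one group and the rest uses the
two-sided Wilcoxon rank-sum test over *all* genes in the universe, with a
Bonferroni correction across that universe. A gene is retained as a
marker when its log2 fold change is at least ``fc_threshold`` (default
0.25) and its adjusted p-value is below ``p_threshold`` (default 0.001).

Fold changes are computed on back-transformed group means: for each
group the mean of ``exp(value) - 1`` over its cells, then
``log2((mean_in + pseudo) / (mean_out + pseudo))`` with a small
pseudocount.

Signature overlaps (e.g. against published disease-associated or
injury-responsive microglia gene sets) report exact set sizes plus a
one-sided hypergeometric enrichment p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, log2, sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, ValidationError
from .normalize import NormalizedMatrix

#: switch from exhaustive enumeration to the normal approximation when the
#: number of rank assignments C(n, n_a) exceeds this
EXACT_ENUMERATION_LIMIT = 10_000


def wilcoxon_rank_sum(a, b, exact_limit: int = EXACT_ENUMERATION_LIMIT):
    """Two-sided Wilcoxon rank-sum test of two samples.

    Ranks use midranks for ties. When the number of distinct rank
    assignments ``C(|a|+|b|, |a|)`` is at most ``exact_limit`` the p-value
    is computed by exhaustive enumeration of all assignments (valid with
    ties); otherwise a normal approximation with tie correction and
    continuity correction is used. Returns ``(rank_sum_of_a, p_two_sided)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both samples must be non-empty")
    na, nb = a.size, b.size
    n = na + nb
    ranks = stats.rankdata(np.concatenate([a, b]))
    W = float(ranks[:na].sum())
    mu = na * (n + 1) / 2.0

    if comb(n, na) <= exact_limit:
        d = abs(W - mu)
        total = hits = 0
        for idx in combinations(range(n), na):
            s = sum(ranks[i] for i in idx)
            total += 1
            if abs(s - mu) >= d - 1e-9:
                hits += 1
        return W, hits / total

    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # every pooled value tied
        return W, 1.0
    z = (abs(W - mu) - 0.5) / sqrt(var)
    z = max(z, 0.0)
    return W, min(1.0, 2.0 * stats.norm.sf(z))


def log2_fold_change(mean_in: float, mean_out: float, pseudo: float = 1e-9) -> float:
    """``log2((mean_in + pseudo) / (mean_out + pseudo))`` on natural-scale means."""
    if pseudo <= 0:
        raise ParameterError("pseudocount must be positive")
    if mean_in < 0 or mean_out < 0:
        raise ParameterError("group means must be non-negative")
    return log2((mean_in + pseudo) / (mean_out + pseudo))


@dataclass
class MarkerResult:
    """Differential-expression record for one gene in one group-vs-rest test."""

    gene: str
    group: str
    log2fc: float
    p_raw: float
    p_adj: float
    mean_in: float
    mean_out: float
    retained: bool


def find_markers(
    norm: NormalizedMatrix,
    labels,
    target: str,
    fc_threshold: float = 0.25,
    p_threshold: float = 1e-3,
    pseudo: float = 1e-9,
) -> list[MarkerResult]:
    """Group-vs-rest differential expression over the full gene universe.

    ``labels`` assigns a group label to every cell of ``norm`` (array-like
    in cell order, or a mapping/Series keyed by cell id). One
    :class:`MarkerResult` per gene; Bonferroni n is the number of genes
    tested (the whole universe). Deterministic.
    """
    if isinstance(labels, (dict, pd.Series)):
        labels = pd.Series(labels).loc[norm.cell_ids].to_numpy()
    labels = np.asarray(labels, dtype=object)
    if labels.size != norm.n_cells:
        raise ValidationError(f"{labels.size} labels for {norm.n_cells} cells")
    in_mask = labels == target
    if not in_mask.any():
        raise ValidationError(f"target group {target!r} has no cells")
    if in_mask.all():
        raise ValidationError("every cell is in the target group; no complement to test")

    n_genes = norm.n_genes
    X_in = norm.values[:, in_mask]
    X_out = norm.values[:, ~in_mask]
    mean_in = np.expm1(X_in).mean(axis=1)
    mean_out = np.expm1(X_out).mean(axis=1)

    results = []
    for g in range(n_genes):
        _, p_raw = wilcoxon_rank_sum(X_in[g], X_out[g])
        p_adj = min(1.0, p_raw * n_genes)
        lfc = log2_fold_change(float(mean_in[g]), float(mean_out[g]), pseudo)
        results.append(
            MarkerResult(
                gene=norm.gene_ids[g],
                group=str(target),
                log2fc=lfc,
                p_raw=p_raw,
                p_adj=p_adj,
                mean_in=float(mean_in[g]),
                mean_out=float(mean_out[g]),
                retained=(lfc >= fc_threshold) and (p_adj < p_threshold),
            )
        )
    return results


def markers_to_frame(results: list[MarkerResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def retained_genes(results: list[MarkerResult]) -> list[str]:
    """Genes passing the marker thresholds, in input order."""
    return [r.gene for r in results if r.retained]


def enrichment_genes(results: list[MarkerResult], p_adj_max: float = 0.05) -> list[str]:
    """Genes selected as input for downstream enrichment (adjusted p cut only)."""
    return [r.gene for r in results if r.p_adj < p_adj_max]


@dataclass
class SignatureOverlap:
    """Exact overlap bookkeeping of two gene sets within a common universe."""

    set_a_size: int
    set_b_size: int
    intersection_size: int
    union_size: int
    universe_size: int
    enrichment_p: float


def signature_overlap(set_a, set_b, universe) -> SignatureOverlap:
    """Shared/unique tabulation of two gene sets plus hypergeometric enrichment.

    ``enrichment_p`` is the one-sided upper-tail probability of drawing at
    least the observed intersection when ``|set_b|`` genes are sampled
    without replacement from a universe containing ``|set_a|`` successes.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        stray = sorted((set_a | set_b) - universe)
        raise ValidationError(f"gene set member(s) outside the universe: {stray[:5]}")
    k = len(set_a & set_b)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(set_a), len(set_b)))
    return SignatureOverlap(
        set_a_size=len(set_a),
        set_b_size=len(set_b),
        intersection_size=k,
        union_size=len(set_a | set_b),
        universe_size=len(universe),
        enrichment_p=min(p, 1.0),
    )
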