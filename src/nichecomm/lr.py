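"""Ligand-receptor cross-talk screen with a label-permutation null.

The interaction score for a pair (L, R) between a sender and a receiver
population at one time point is

    score = ( mean_L(sender, t) + mean_R(receiver, t) ) / 2

where ``mean`` is the average log-normalized expression over all cells of
the group. Significance comes from a permutation test: the joint
``(cell_type, time_point)`` label vector is shuffled across cells
``n_perm`` times (default 1000), the group means are recomputed under each
shuffle, and every configured pair is rescored — one shuffle serves all
pairs. The empirical p-value is the proportion of null scores greater than
or equal to the observed score (ties count, p = 0 is attainable).

Shuffling the joint label moves cell type and time point together, which
preserves the co-occurrence structure of the two classifications; an
``independent`` shuffle mode that permutes the two label columns
separately is available for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CellAnnotation, LRPairTable
from .errors import ParameterError, ValidationError
from .normalize import GroupMeans, NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    """Configuration of one cross-talk screen.

    sender_type / receiver_type
        The two cell populations; with ``direction_mode="both-directions"``
        (default) each pair is scored with the ligand in either population,
        yielding two records per pair and time point.
    time_points
        Time points to score (default: every time point observed in the
        annotation, in vocabulary order).
    n_perm
        Number of label shuffles for the null (default 1000).
    shuffle_mode
        ``"joint"`` permutes the joint (cell_type, time_point) label vector
        (default); ``"independent"`` permutes the two columns separately.
    smooth_p
        If set, report (count + 1) / (n_perm + 1) instead of the raw
        proportion; off by default so p = 0 is attainable.
    keep_null
        Attach the full null score vector to every result (otherwise only
        summary statistics are kept).
    """

    sender_type: str
    receiver_type: str
    time_points: tuple[str, ...] | None = None
    n_perm: int = 1000
    seed: int = 0
    direction_mode: str = "both-directions"
    shuffle_mode: str = "joint"
    smooth_p: bool = False
    keep_null: bool = False

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ParameterError("n_perm must be >= 1")
        if self.direction_mode not in ("both-directions", "ligand-in-sender"):
            raise ParameterError(f"unknown direction_mode {self.direction_mode!r}")
        if self.shuffle_mode not in ("joint", "independent"):
            raise ParameterError(f"unknown shuffle_mode {self.shuffle_mode!r}")


@dataclass
class InteractionResult:
    """One scored (ligand -> receptor, sender -> receiver, time point) record."""

    ligand: str
    receptor: str
    sender: str
    receiver: str
    time_point: str
    score: float
    p_value: float
    n_perm: int
    count_ge: int
    null_mean: float
    null_max: float
    null_scores: np.ndarray | None = field(default=None, repr=False)


def interaction_score(
    gm: GroupMeans, ligand: str, receptor: str, sender: str, receiver: str, time_point: str
) -> float:
    """Mean of the two group-average expressions defining the pair's score.

    A gene absent from the gene universe contributes a mean of 0 with a
    logged warning; an unknown group raises ``KeyError``.
    """
    means = []
    for gene, cell_type in ((ligand, sender), (receptor, receiver)):
        if (cell_type, time_point) not in gm.means.columns:
            raise KeyError(
                f"no cells in group (cell_type={cell_type!r}, time_point={time_point!r})"
            )
        if gene not in gm.means.index:
            logger.warning("gene %r not in the gene universe; mean taken as 0", gene)
            means.append(0.0)
        else:
            means.append(gm.get(cell_type, time_point, gene))
    return 0.5 * (means[0] + means[1])


def empirical_pvalue(observed: float, null_scores: np.ndarray, smooth: bool = False) -> float:
    """Proportion of null scores >= the observed score (ties count as >=)."""
    null_scores = np.asarray(null_scores, dtype=float)
    if null_scores.size == 0:
        raise ParameterError("null score collection is empty")
    count = int((null_scores >= observed).sum())
    if smooth:
        return (count + 1) / (null_scores.size + 1)
    return count / null_scores.size


# ---------------------------------------------------------------------------
# internal machinery shared by permutation_null and screen


def _conditions(pairs: LRPairTable, gene_index: dict, cfg: ScreenConfig, time_points):
    """Testable (ligand, receptor, sender, receiver, t) tuples, de-duplicated."""
    directions = [(cfg.sender_type, cfg.receiver_type)]
    if cfg.direction_mode == "both-directions" and cfg.sender_type != cfg.receiver_type:
        directions.append((cfg.receiver_type, cfg.sender_type))
    conds, seen = [], set()
    n_untestable = 0
    for ligand, receptor in pairs.pairs():
        if ligand not in gene_index or receptor not in gene_index:
            n_untestable += 1
            continue
        for t in time_points:
            for snd, rcv in directions:
                key = (ligand, receptor, snd, rcv, t)
                if key not in seen:
                    seen.add(key)
                    conds.append(key)
    if n_untestable:
        logger.warning("%d pair(s) with genes outside the universe skipped", n_untestable)
    if not conds:
        raise ValidationError("no testable pairs: no pair has both genes in the gene universe")
    return conds


class _Screen:
    """Precomputed state for scoring observed and permuted labelings."""

    def __init__(
        self,
        norm: NormalizedMatrix,
        ann: CellAnnotation,
        pairs: LRPairTable,
        cfg: ScreenConfig,
    ):
        self.cfg = cfg
        labels = ann.align(norm.cell_ids)
        observed_tps = [t for t in ann.time_points if t in set(labels["time_point"])]
        self.time_points = tuple(cfg.time_points) if cfg.time_points else tuple(observed_tps)

        gene_index = {g: i for i, g in enumerate(norm.gene_ids)}
        self.conditions = _conditions(pairs, gene_index, cfg, self.time_points)

        # restrict the matrix to the genes any condition touches
        needed = sorted({c[0] for c in self.conditions} | {c[1] for c in self.conditions})
        self.row_of = {g: i for i, g in enumerate(needed)}
        self.X = norm.values[[gene_index[g] for g in needed], :]

        ct = labels["cell_type"].to_numpy()
        tp = labels["time_point"].to_numpy()
        self.groups = sorted(set(zip(ct, tp)))
        self.group_of = {g: i for i, g in enumerate(self.groups)}
        self.group_pos = [
            np.flatnonzero((ct == c) & (tp == t)) for c, t in self.groups
        ]
        self.ct_codes = ct
        self.tp_codes = tp

        for _, _, snd, rcv, t in self.conditions:
            for cell_type in (snd, rcv):
                if (cell_type, t) not in self.group_of:
                    raise KeyError(
                        f"no cells in group (cell_type={cell_type!r}, time_point={t!r})"
                    )

        self.lig_rows = np.array([self.row_of[c[0]] for c in self.conditions])
        self.rec_rows = np.array([self.row_of[c[1]] for c in self.conditions])
        self.snd_gid = np.array([self.group_of[(c[2], c[4])] for c in self.conditions])
        self.rcv_gid = np.array([self.group_of[(c[3], c[4])] for c in self.conditions])

    def _scores_from_group_means(self, G: np.ndarray) -> np.ndarray:
        return 0.5 * (G[self.lig_rows, self.snd_gid] + G[self.rec_rows, self.rcv_gid])

    def observed_scores(self) -> np.ndarray:
        G = np.column_stack([self.X[:, pos].mean(axis=1) for pos in self.group_pos])
        return self._scores_from_group_means(G)

    def null_scores(self, rng: np.random.Generator) -> np.ndarray:
        """(n_perm x n_conditions) matrix of null scores."""
        n_cells = self.X.shape[1]
        out = np.empty((self.cfg.n_perm, len(self.conditions)))
        warned_empty = False
        for i in range(self.cfg.n_perm):
            if self.cfg.shuffle_mode == "joint":
                perm = rng.permutation(n_cells)
                G = np.column_stack(
                    [self.X[:, perm[pos]].mean(axis=1) for pos in self.group_pos]
                )
            else:
                ct = self.ct_codes[rng.permutation(n_cells)]
                tp = self.tp_codes[rng.permutation(n_cells)]
                cols = []
                for c, t in self.groups:
                    mask = (ct == c) & (tp == t)
                    if mask.any():
                        cols.append(self.X[:, mask].mean(axis=1))
                    else:
                        if not warned_empty:
                            logger.warning(
                                "independent shuffle produced an empty group; mean taken as 0"
                            )
                            warned_empty = True
                        cols.append(np.zeros(self.X.shape[0]))
                G = np.column_stack(cols)
            out[i] = self._scores_from_group_means(G)
        return out


def permutation_null(
    norm: NormalizedMatrix, ann: CellAnnotation, pairs: LRPairTable, cfg: ScreenConfig
) -> tuple[np.ndarray, list[tuple]]:
    """Null interaction scores under ``n_perm`` label shuffles.

    Returns an ``(n_perm, n_conditions)`` array and the condition list
    ``(ligand, receptor, sender, receiver, time_point)`` labelling its
    columns. Deterministic given ``cfg.seed``.
    """
    state = _Screen(norm, ann, pairs, cfg)
    rng = np.random.default_rng(cfg.seed)
    return state.null_scores(rng), state.conditions


def screen(
    norm: NormalizedMatrix, ann: CellAnnotation, pairs: LRPairTable, cfg: ScreenConfig
) -> list[InteractionResult]:
    """Score every testable pair per time point (and direction) with empirical p.

    One list entry per (pair x time point x direction); identical inputs
    and seed reproduce the identical result list.
    """
    state = _Screen(norm, ann, pairs, cfg)
    rng = np.random.default_rng(cfg.seed)
    observed = state.observed_scores()
    null = state.null_scores(rng)
    counts = (null >= observed[None, :]).sum(axis=0)
    results = []
    for j, (ligand, receptor, snd, rcv, t) in enumerate(state.conditions):
        c = int(counts[j])
        p = (c + 1) / (cfg.n_perm + 1) if cfg.smooth_p else c / cfg.n_perm
        results.append(
            InteractionResult(
                ligand=ligand,
                receptor=receptor,
                sender=snd,
                receiver=rcv,
                time_point=t,
                score=float(observed[j]),
                p_value=float(p),
                n_perm=cfg.n_perm,
                count_ge=c,
                null_mean=float(null[:, j].mean()),
                null_max=float(null[:, j].max()),
                null_scores=null[:, j].copy() if cfg.keep_null else None,
            )
        )
    return results


def results_to_frame(results: list[InteractionResult]) -> pd.DataFrame:
    """Flat table of the screen output (the machine-readable dot-plot twin)."""
    return pd.DataFrame(
        [
            {
                "ligand": r.ligand,
                "receptor": r.receptor,
                "sender": r.sender,
                "receiver": r.receiver,
                "time_point": r.time_point,
                "score": r.score,
                "p_value": r.p_value,
                "n_perm": r.n_perm,
            }
            for r in results
        ]
    )


def chord_adjacency(
    results: list[InteractionResult], p_max: float, weight: str = "count"
) -> pd.DataFrame:
    """Sender x receiver adjacency of interactions with p <= ``p_max``.

    Entries count passing interactions (``weight="count"``) or sum their
    scores (``weight="score"``) — the tabular form of a chord diagram.
    """
    if weight not in ("count", "score"):
        raise ParameterError(f"unknown weight {weight!r}")
    if not results:
        raise ParameterError("empty result list")
    labels = sorted({r.sender for r in results} | {r.receiver for r in results})
    adj = pd.DataFrame(0.0, index=labels, columns=labels)
    for r in results:
        if r.p_value <= p_max:
            adj.at[r.sender, r.receiver] += 1 if weight == "count" else r.score
    return adj
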