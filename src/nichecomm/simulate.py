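"""Seeded generator of synthetic plate-based single-cell UMI data.

The generator emulates the structure of a sorted two-population stroke
time-course experiment: three 384-well plates (1152 wells) of microglia
and neural stem/precursor cells collected uninjured and at days 1 and 7
after photothrombotic injury. Counts are negative-binomial (gene-level
means drawn log-normally, shared dispersion) with a bounded per-cell
capture-efficiency factor. On top of the baseline it can plant

- **ligand-receptor co-expression**: a pair's ligand mean is multiplied
  by ``fold`` in the (sender, time_point) group and its receptor mean in
  the (receiver, time_point) group;
- **cluster markers**: a gene's mean is multiplied by ``fold`` in one
  cell type;
- **doublets**: a well's column is replaced by the sum of two
  independently drawn cells' counts;
- **dying cells**: the mitochondrial share of the library is re-allocated
  to ~40%, above the 25% QC ceiling.

Everything planted is recorded in a :class:`SyntheticTruth` so recovery
tests are self-contained. Identical config + seed reproduce identical
output bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    DEFAULT_CELL_TYPES,
    DEFAULT_TIME_POINTS,
    CellAnnotation,
    CountMatrix,
)
from .errors import ParameterError

#: The 13 protein-coding genes of the mouse mitochondrial genome; used as
#: the reserved ``mt-`` block so QC prefix matching is exercised.
MOUSE_MITO_GENES: tuple[str, ...] = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Co3", "mt-Atp6", "mt-Atp8",
    "mt-Cytb", "mt-Nd3", "mt-Nd4", "mt-Nd4l", "mt-Nd5", "mt-Nd6",
)


@dataclass(frozen=True)
class PlantedPair:
    """A ligand-receptor co-expression effect to plant."""

    ligand: str
    receptor: str
    sender: str
    receiver: str
    time_point: str
    fold: float = 4.0


@dataclass(frozen=True)
class PlantedMarker:
    """A cell-type marker effect to plant."""

    gene: str
    cell_type: str
    fold: float = 3.0


@dataclass
class SimConfig:
    """Study-design and noise parameters of the generator.

    Defaults mirror the emulated experiment: 3 plates x 384 wells (1152
    cells), two sorted populations in equal proportion, three time points
    in equal proportion, ~2000 detected genes with a mean of 2 UMIs per
    gene per cell (libraries of roughly 4000 UMIs, typical of plate-based
    UMI protocols), negative-binomial dispersion theta = 10, healthy
    mitochondrial share 5%, and 5% each of doublets and dying cells.
    """

    n_plates: int = 3
    wells_per_plate: int = 384
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    cell_type_props: tuple[float, ...] = (0.5, 0.5)
    time_points: tuple[str, ...] = DEFAULT_TIME_POINTS
    time_point_props: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    n_genes: int = 2000
    baseline_mean: float = 2.0
    baseline_sigma: float = 1.0
    nb_theta: float = 10.0
    size_factor_range: tuple[float, float] = (0.7, 1.3)
    n_mito_genes: int = 13
    mito_frac_healthy: float = 0.05
    mito_frac_dying: float = 0.40
    doublet_rate: float = 0.05
    dying_rate: float = 0.05
    planted_pairs: tuple[PlantedPair, ...] = ()
    planted_markers: tuple[PlantedMarker, ...] = ()
    planted_base_mean: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plates < 1 or self.wells_per_plate < 1 or self.n_genes < 1:
            raise ParameterError("plate, well and gene counts must be positive")
        for props, vocab, what in (
            (self.cell_type_props, self.cell_types, "cell_type"),
            (self.time_point_props, self.time_points, "time_point"),
        ):
            if len(props) != len(vocab):
                raise ParameterError(f"{what} proportions do not match vocabulary")
            if abs(sum(props) - 1.0) > 1e-9:
                raise ParameterError(f"{what} proportions must sum to 1")
        for rate, what in ((self.doublet_rate, "doublet"), (self.dying_rate, "dying")):
            if not (0 <= rate < 1):
                raise ParameterError(f"{what}_rate must lie in [0, 1)")
        for p in self.planted_pairs:
            if p.fold <= 1:
                raise ParameterError("planted pair fold must exceed 1")
        for m in self.planted_markers:
            if m.fold <= 1:
                raise ParameterError("planted marker fold must exceed 1")
        if not (0 < self.mito_frac_healthy < self.mito_frac_dying < 1):
            raise ParameterError("need 0 < mito_frac_healthy < mito_frac_dying < 1")
        if self.n_mito_genes < 1 or self.n_mito_genes >= self.n_genes:
            raise ParameterError("n_mito_genes must lie in [1, n_genes)")

    @property
    def n_cells(self) -> int:
        return self.n_plates * self.wells_per_plate


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset, for recovery tests."""

    labels: pd.DataFrame  # index cell_id; columns cell_type, time_point
    doublet_ids: list[str]
    dying_ids: list[str]
    planted_pairs: tuple[PlantedPair, ...]
    planted_markers: tuple[PlantedMarker, ...]
    seed: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "doublet_ids": list(self.doublet_ids),
            "dying_ids": list(self.dying_ids),
            "planted_pairs": [dataclasses.asdict(p) for p in self.planted_pairs],
            "planted_markers": [dataclasses.asdict(m) for m in self.planted_markers],
            "labels": {
                cid: {"cell_type": row.cell_type, "time_point": row.time_point}
                for cid, row in self.labels.iterrows()
            },
        }

    def write_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def gene_universe(cfg: SimConfig) -> list[str]:
    """Gene identifiers the generator will emit, in matrix row order."""
    n_plain = cfg.n_genes - cfg.n_mito_genes
    plain = [f"g{i + 1:04d}" for i in range(n_plain)]
    mito = list(MOUSE_MITO_GENES[: cfg.n_mito_genes])
    while len(mito) < cfg.n_mito_genes:  # beyond the 13 real symbols
        mito.append(f"mt-x{len(mito) + 1}")
    return plain + mito


def _planted_genes(cfg: SimConfig) -> set[str]:
    genes = {m.gene for m in cfg.planted_markers}
    for p in cfg.planted_pairs:
        genes.add(p.ligand)
        genes.add(p.receptor)
    return genes


def generate(cfg: SimConfig) -> tuple[CountMatrix, CellAnnotation, SyntheticTruth]:
    """Draw one synthetic dataset; deterministic given ``cfg`` (incl. seed)."""
    genes = gene_universe(cfg)
    gene_set = set(genes)
    missing = sorted(_planted_genes(cfg) - gene_set)
    if missing:
        raise ParameterError(f"planted gene(s) not in the universe: {missing[:5]}")
    for p in cfg.planted_pairs:
        if p.sender not in cfg.cell_types or p.receiver not in cfg.cell_types:
            raise ParameterError(f"planted pair group outside cell_types: {p}")
        if p.time_point not in cfg.time_points:
            raise ParameterError(f"planted pair time point outside vocabulary: {p}")
    for m in cfg.planted_markers:
        if m.cell_type not in cfg.cell_types:
            raise ParameterError(f"planted marker cell type outside vocabulary: {m}")

    rng = np.random.default_rng(cfg.seed)
    n_cells, n_genes = cfg.n_cells, cfg.n_genes
    n_mito = cfg.n_mito_genes
    cell_ids = [
        f"plate{p + 1}_well{w + 1:03d}"
        for p in range(cfg.n_plates)
        for w in range(cfg.wells_per_plate)
    ]

    cell_type = rng.choice(cfg.cell_types, size=n_cells, p=cfg.cell_type_props)
    time_point = rng.choice(cfg.time_points, size=n_cells, p=cfg.time_point_props)

    # gene baseline means: log-normal with E = baseline_mean; planted genes get
    # a fixed well-detected baseline; the mt- block is scaled so the expected
    # mitochondrial share of a healthy library is mito_frac_healthy
    z = rng.normal(size=n_genes - n_mito)
    base = cfg.baseline_mean * np.exp(cfg.baseline_sigma * z - cfg.baseline_sigma**2 / 2)
    base = np.concatenate([base, np.zeros(n_mito)])
    for g in _planted_genes(cfg):
        base[genes.index(g)] = cfg.planted_base_mean
    t_plain = base[: n_genes - n_mito].sum()
    base[n_genes - n_mito:] = (
        cfg.mito_frac_healthy / (1 - cfg.mito_frac_healthy) * t_plain / n_mito
    )

    size_factor = rng.uniform(*cfg.size_factor_range, size=n_cells)

    def group_fold(ct: np.ndarray, tp: np.ndarray) -> np.ndarray:
        """Per-(gene, cell) fold multipliers from the planted effects."""
        fold = np.ones((n_genes, ct.size))
        for m in cfg.planted_markers:
            fold[genes.index(m.gene), ct == m.cell_type] *= m.fold
        for p in cfg.planted_pairs:
            fold[genes.index(p.ligand), (ct == p.sender) & (tp == p.time_point)] *= p.fold
            fold[genes.index(p.receptor), (ct == p.receiver) & (tp == p.time_point)] *= p.fold
        return fold

    mean = base[:, None] * size_factor[None, :] * group_fold(cell_type, time_point)

    # disjoint doublet / dying wells
    n_doublet = int(round(cfg.doublet_rate * n_cells))
    n_dying = int(round(cfg.dying_rate * n_cells))
    perm = rng.permutation(n_cells)
    doublet_idx = np.sort(perm[:n_doublet])
    dying_idx = np.sort(perm[n_doublet: n_doublet + n_dying])

    if n_dying:
        col = mean[:, dying_idx]
        mito_share = col[n_genes - n_mito:].sum(axis=0) / col.sum(axis=0)
        col[n_genes - n_mito:] *= cfg.mito_frac_dying / mito_share
        col[: n_genes - n_mito] *= (1 - cfg.mito_frac_dying) / (1 - mito_share)
        mean[:, dying_idx] = col

    lam = rng.gamma(cfg.nb_theta, mean / cfg.nb_theta)
    counts = rng.poisson(lam).astype(np.int64)

    if n_doublet:
        # the second cell of each doublet well: fresh labels, size factor and draw
        ct2 = rng.choice(cfg.cell_types, size=n_doublet, p=cfg.cell_type_props)
        tp2 = rng.choice(cfg.time_points, size=n_doublet, p=cfg.time_point_props)
        sf2 = rng.uniform(*cfg.size_factor_range, size=n_doublet)
        mean2 = base[:, None] * sf2[None, :] * group_fold(ct2, tp2)
        lam2 = rng.gamma(cfg.nb_theta, mean2 / cfg.nb_theta)
        counts[:, doublet_idx] += rng.poisson(lam2).astype(np.int64)

    labels = pd.DataFrame(
        {"cell_type": cell_type, "time_point": time_point},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    truth = SyntheticTruth(
        labels=labels,
        doublet_ids=[cell_ids[i] for i in doublet_idx],
        dying_ids=[cell_ids[i] for i in dying_idx],
        planted_pairs=tuple(cfg.planted_pairs),
        planted_markers=tuple(cfg.planted_markers),
        seed=cfg.seed,
    )
    matrix = CountMatrix(counts, genes, cell_ids)
    annotation = CellAnnotation(
        labels.copy(), cell_types=cfg.cell_types, time_points=cfg.time_points
    )
    return matrix, annotation, truth


def null_dataset(cfg: SimConfig) -> tuple[CountMatrix, CellAnnotation, SyntheticTruth]:
    """As :func:`generate` with every planted effect and artifact disabled.

    The result is label-exchangeable: cell type and time point carry no
    expression information, making it the input for type-I-error
    calibration.
    """
    null_cfg = dataclasses.replace(
        cfg, doublet_rate=0.0, dying_rate=0.0, planted_pairs=(), planted_markers=()
    )
    return generate(null_cfg)
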