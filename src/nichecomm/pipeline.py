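"""End-to-end orchestration: qc -> normalize -> screen -> markers -> report.

A run is driven by a config mapping (YAML or JSON on disk), executes the
five stages in fixed order into an output directory, and finishes by
writing a machine-readable manifest listing every produced file with its
content hash, the config hash and the seed. Re-running with an identical
config and seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import io as ncio
from .containers import DEFAULT_CELL_TYPES, DEFAULT_TIME_POINTS
from .errors import ParameterError, PipelineError
from .lr import ScreenConfig, chord_adjacency, results_to_frame, screen
from .markers import find_markers, markers_to_frame, retained_genes, signature_overlap
from .normalize import group_means, log_normalize
from .orthologs import map_orthologs
from .qc import QCParams, apply_qc

STAGES = ("qc", "normalize", "screen", "markers", "report")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    counts: dict  # {"matrix","features","barcodes"} or {"dense": path}
    annotation: str
    pairs: str
    out: str
    seed: int = 0
    orthologs: str | None = None
    ortholog_policy: str = "expand"
    cell_types: tuple[str, ...] | None = DEFAULT_CELL_TYPES
    time_points: tuple[str, ...] = DEFAULT_TIME_POINTS
    qc: QCParams = field(default_factory=QCParams)
    scale_factor: float = 10_000.0
    screen: dict = field(default_factory=dict)  # sender, receiver, n_perm, ...
    markers: dict = field(default_factory=dict)  # group_by, targets, thresholds
    p_max: float = 0.05  # chord adjacency cut

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "qc" in d and isinstance(d["qc"], dict):
            d["qc"] = QCParams(**d["qc"])
        for key in ("cell_types", "time_points"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
        return cls.from_dict(d)

    def validate_paths(self) -> None:
        paths = list(self.counts.values()) + [self.annotation, self.pairs]
        if self.orthologs:
            paths.append(self.orthologs)
        missing = [p for p in paths if not os.path.exists(p)]
        if missing:
            raise ParameterError(f"input path(s) not found: {missing}")

    def to_jsonable(self) -> dict:
        return dataclasses.asdict(self)


def config_hash(cfg: RunConfig) -> str:
    """Hash of the analysis-relevant config (the output path is excluded)."""
    d = cfg.to_jsonable()
    d.pop("out", None)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: str, meta: dict, index: bool = False) -> None:
    """TSV with ``# key=value`` comment header carrying seed and config hash."""
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=index)


def run(cfg: RunConfig) -> dict:
    """Execute all stages and return the manifest (also written to disk).

    Any stage error aborts the run with a stage-named
    :class:`~nichecomm.errors.PipelineError`; the manifest written on
    failure flags the run as incomplete.
    """
    cfg.validate_paths()
    os.makedirs(cfg.out, exist_ok=True)
    chash = config_hash(cfg)
    meta = {"seed": cfg.seed, "config_hash": chash}
    manifest: dict = {
        "config_hash": chash,
        "seed": cfg.seed,
        "complete": False,
        "stages": [],
        "files": {},
    }
    produced: list[str] = []

    def finish_stage(name: str, files: list[str]) -> None:
        manifest["stages"].append({"name": name, "status": "completed"})
        produced.extend(files)

    def fail(stage: str, exc: Exception) -> None:
        manifest["stages"].append({"name": stage, "status": "failed", "error": str(exc)})
        _write_manifest(manifest, produced, cfg.out)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- qc ---------------------------------------------------------------
    try:
        if "dense" in cfg.counts:
            counts = ncio.read_counts_dense(cfg.counts["dense"])
        else:
            counts = ncio.read_counts_mtx(
                cfg.counts["matrix"], cfg.counts["features"], cfg.counts["barcodes"]
            )
        ann = ncio.read_annotation(
            cfg.annotation, cell_types=cfg.cell_types, time_points=cfg.time_points
        )
        filtered, report = apply_qc(counts, cfg.qc)
        qc_dir = os.path.join(cfg.out, "filtered")
        paths = ncio.write_counts_mtx(filtered, qc_dir)
        report_path = os.path.join(cfg.out, "qc_report.json")
        with open(report_path, "w") as fh:
            json.dump({**meta, **report.to_dict()}, fh, indent=1, sort_keys=True)
        finish_stage("qc", list(paths.values()) + [report_path])
    except Exception as exc:  # noqa: BLE001 - every stage error is reported by stage
        fail("qc", exc)

    # --- normalize --------------------------------------------------------
    try:
        norm = log_normalize(filtered, cfg.scale_factor)
        gm = group_means(norm, ann)
        gm_path = os.path.join(cfg.out, "group_means.tsv")
        _write_tsv(gm.to_long(), gm_path, meta)
        finish_stage("normalize", [gm_path])
    except Exception as exc:  # noqa: BLE001
        fail("normalize", exc)

    # --- screen -----------------------------------------------------------
    try:
        pairs = ncio.read_lr_pairs(cfg.pairs)
        if cfg.orthologs:
            omap = ncio.read_ortholog_map(cfg.orthologs)
            pairs, _ = map_orthologs(pairs, omap, policy=cfg.ortholog_policy)
        scfg = ScreenConfig(seed=cfg.seed, **cfg.screen)
        results = screen(norm, ann, pairs, scfg)
        res_path = os.path.join(cfg.out, "interactions.tsv")
        _write_tsv(results_to_frame(results), res_path, meta)
        chord = chord_adjacency(results, p_max=cfg.p_max)
        chord_path = os.path.join(cfg.out, "chord_adjacency.csv")
        chord.to_csv(chord_path)
        finish_stage("screen", [res_path, chord_path])
    except Exception as exc:  # noqa: BLE001
        fail("screen", exc)

    # --- markers ----------------------------------------------------------
    try:
        mcfg = dict(cfg.markers)
        group_by = mcfg.get("group_by", "cell_type")
        labels = ann.align(norm.cell_ids)[group_by]
        targets = mcfg.get("targets") or sorted(labels.unique())
        fc = mcfg.get("fc_threshold", 0.25)
        pthr = mcfg.get("p_threshold", 1e-3)
        marker_files = []
        sets = {}
        for target in targets:
            res = find_markers(norm, labels.to_numpy(), target, fc, pthr)
            path = os.path.join(cfg.out, f"markers_{target}.tsv")
            _write_tsv(markers_to_frame(res), path, meta)
            marker_files.append(path)
            sets[target] = set(retained_genes(res))
        if len(sets) >= 2:
            universe = set(norm.gene_ids)
            rows = []
            names = sorted(sets)
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    ov = dataclasses.asdict(signature_overlap(sets[a], sets[b], universe))
                    rows.append({"set_a": a, "set_b": b, **ov})
            ov_path = os.path.join(cfg.out, "overlap.tsv")
            _write_tsv(pd.DataFrame(rows), ov_path, meta)
            marker_files.append(ov_path)
        finish_stage("markers", marker_files)
    except Exception as exc:  # noqa: BLE001
        fail("markers", exc)

    # --- report -----------------------------------------------------------
    manifest["stages"].append({"name": "report", "status": "completed"})
    manifest["complete"] = True
    _write_manifest(manifest, produced, cfg.out)
    return manifest


def _write_manifest(manifest: dict, produced: list[str], out_dir: str) -> None:
    manifest["files"] = {
        os.path.relpath(p, out_dir): _sha256(p) for p in produced if os.path.exists(p)
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
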