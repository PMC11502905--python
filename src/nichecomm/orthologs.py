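"""Ortholog translation of ligand-receptor pair tables.

Reference ligand-receptor lists are curated on human gene symbols; applying
them to mouse data requires translating both members of every pair through
an ortholog table. The mapping is consumed as a precomputed two-column
table (e.g. a biomaRt export) rather than queried live.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .containers import LRPairTable, OrthologMap
from .errors import ParameterError


@dataclass
class MappingReport:
    """Bookkeeping for one :func:`map_orthologs` call."""

    n_input: int
    n_output: int
    n_dropped: int
    policy: str
    dropped_pairs: list = field(default_factory=list)
    n_expanded: int = 0  # pairs whose one-to-many mapping emitted > 1 output pair


def map_orthologs(
    pairs: LRPairTable, omap: OrthologMap, policy: str = "expand"
) -> tuple[LRPairTable, MappingReport]:
    """Translate every pair through the ortholog map.

    A pair is emitted only when both its ligand and its receptor map;
    unmapped pairs are dropped and counted in the report, never fatal.
    One-to-many orthologs are handled per ``policy``:

    - ``"expand"`` (default): emit the Cartesian product of mapped ligand
      and receptor symbols, de-duplicated in first-seen order;
    - ``"drop"``: drop any pair whose ligand or receptor maps ambiguously.
    """
    if policy not in ("expand", "drop"):
        raise ParameterError(f"unknown one-to-many policy {policy!r}")
    out_rows: list[dict] = []
    seen: set[tuple[str, str]] = set()
    report = MappingReport(n_input=len(pairs), n_output=0, n_dropped=0, policy=policy)
    has_pathway = "pathway" in pairs.table.columns
    for row in pairs.table.itertuples(index=False):
        ligands = omap.targets(row.ligand)
        receptors = omap.targets(row.receptor)
        if not ligands or not receptors:
            report.n_dropped += 1
            report.dropped_pairs.append((row.ligand, row.receptor))
            continue
        if policy == "drop" and (len(ligands) > 1 or len(receptors) > 1):
            report.n_dropped += 1
            report.dropped_pairs.append((row.ligand, row.receptor))
            continue
        n_emitted = 0
        for lig in ligands:
            for rec in receptors:
                if (lig, rec) in seen:
                    continue
                seen.add((lig, rec))
                rec_row = {"ligand": lig, "receptor": rec}
                if has_pathway:
                    rec_row["pathway"] = row.pathway
                out_rows.append(rec_row)
                n_emitted += 1
        if n_emitted > 1:
            report.n_expanded += 1
    report.n_output = len(out_rows)
    cols = ["ligand", "receptor"] + (["pathway"] if has_pathway else [])
    out = pd.DataFrame(out_rows, columns=cols)
    return LRPairTable(out), report
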