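"""Docking-score table summaries and binding-affinity classification.

This module analyzes tables of precomputed ligand–receptor binding free
energies (kcal/mol, more negative = stronger predicted binding); it does
not run docking.  Affinity classes follow the customary score cutoffs:
below −7 strong, below −5 good, below −4.25 binding, otherwise none —
each "below" strict, so a boundary value falls in the weaker class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DockingTable",
    "read_docking_table",
    "write_docking_table",
    "best_per_target",
    "global_extremes",
    "classify_affinity",
    "summarize",
    "AFFINITY_CUTOFFS",
]

#: (threshold, class) pairs; a score strictly below the threshold earns the class
AFFINITY_CUTOFFS = ((-7.0, "strong"), (-5.0, "good"), (-4.25, "binding"))


@dataclass
class DockingTable:
    """Target x component matrix of binding energies.

    ``targets`` is a list of ``(gene, pdb_id)`` pairs, ``components`` the
    ligand names, and ``scores`` the complete matrix in kcal/mol.
    """

    targets: list[tuple[str, str]]
    components: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.targets), len(self.components)):
            raise ValueError(
                f"score matrix shape {self.scores.shape} != "
                f"({len(self.targets)} targets, {len(self.components)} components)"
            )
        if not np.isfinite(self.scores).all():
            raise ValueError("docking scores must be finite (incomplete table)")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=self.components)
        df.insert(0, "target", [t for t, _ in self.targets])
        df.insert(1, "pdb_id", [p for _, p in self.targets])
        return df


def read_docking_table(path: str | Path) -> DockingTable:
    """Read a docking TSV: header target, pdb_id, then one column per component."""
    df = pd.read_csv(path, sep="\t", dtype={"target": str, "pdb_id": str})
    if not {"target", "pdb_id"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns target, pdb_id, <components...>")
    components = [c for c in df.columns if c not in ("target", "pdb_id")]
    return DockingTable(
        targets=list(zip(df["target"], df["pdb_id"])),
        components=components,
        scores=df[components].to_numpy(dtype=float),
    )


def write_docking_table(table: DockingTable, path: str | Path) -> None:
    """Write canonical TSV (scores with one decimal place)."""
    with open(path, "w") as fh:
        fh.write("target\tpdb_id\t" + "\t".join(table.components) + "\n")
        for (gene, pdb), row in zip(table.targets, table.scores):
            fh.write(gene + "\t" + pdb + "\t" + "\t".join(f"{v:.1f}" for v in row) + "\n")


def best_per_target(table: DockingTable) -> pd.DataFrame:
    """Per-target minimum score with all tied best components listed.

    Returns columns target, pdb_id, best_score, best_components (comma
    joined, table order), affinity_class.
    """
    rows = []
    for (gene, pdb), scores in zip(table.targets, table.scores):
        best = float(scores.min())
        tied = [c for c, s in zip(table.components, scores) if s == best]
        rows.append((gene, pdb, best, ",".join(tied), classify_affinity(best)))
    return pd.DataFrame(
        rows, columns=["target", "pdb_id", "best_score", "best_components", "affinity_class"]
    )


def global_extremes(table: DockingTable) -> dict:
    """Exact global minimum and maximum with all attaining (target, component) cells."""
    lo, hi = float(table.scores.min()), float(table.scores.max())

    def cells(value: float) -> list[tuple[str, str]]:
        out = []
        for (gene, _), scores in zip(table.targets, table.scores):
            out.extend((gene, c) for c, s in zip(table.components, scores) if s == value)
        return out

    return {"min": lo, "min_cells": cells(lo), "max": hi, "max_cells": cells(hi)}


def classify_affinity(score: float) -> str:
    """Map a binding energy to {strong, good, binding, none} by strict cutoffs."""
    if not np.isfinite(score):
        raise ValueError(f"score must be finite, got {score}")
    for threshold, label in AFFINITY_CUTOFFS:
        if score < threshold:
            return label
    return "none"


def summarize(table: DockingTable) -> pd.DataFrame:
    """Alias for :func:`best_per_target`, the module's summary product."""
    return best_per_target(table)
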