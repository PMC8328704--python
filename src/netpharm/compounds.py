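"""ADME screening of herb ingredients.

Candidate compounds of a herb pair are admitted on two pharmacokinetic
axes: oral bioavailability (OB, percent of an oral dose reaching systemic
circulation) and druglikeness (DL, a Tanimoto-type similarity between a
compound's molecular-descriptor vector and the average descriptor vector
of known drugs).  Compounds passing ``OB >= 30`` and ``DL >= 0.18`` and
possessing at least one annotated protein target form the putative-target
side of the downstream network analysis.

DL values in published compound tables are consumed as data; the
:func:`druglikeness` score is provided for callers who have their own
descriptor vectors (the descriptor set behind published tables is not
recoverable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "druglikeness",
    "filter_compounds",
    "drop_targetless",
    "read_compound_table",
    "write_compound_table",
    "read_target_map",
    "write_target_map",
]


@dataclass(frozen=True)
class CompoundRecord:
    """One herb ingredient with its screening parameters.

    Parameters
    ----------
    mol_id : str
        Molecule identifier, e.g. ``MOL000098``.
    name : str
        Trivial or systematic molecule name.
    herb : str
        Herb-of-origin label (``AR``, ``PN`` or ``AR+PN``).
    OB : float
        Oral bioavailability in percent, ``>= 0``.
    DL : float
        Druglikeness index in ``[0, 1]``.
    """

    mol_id: str
    name: str
    herb: str
    OB: float
    DL: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.OB) or self.OB < 0:
            raise ValueError(f"{self.mol_id}: OB must be finite and >= 0, got {self.OB}")
        if not np.isfinite(self.DL) or not 0.0 <= self.DL <= 1.0:
            raise ValueError(f"{self.mol_id}: DL must be in [0, 1], got {self.DL}")


def druglikeness(x: Sequence[float], y: Sequence[float]) -> float:
    """Tanimoto druglikeness score between two descriptor vectors.

    ``DL(x, y) = x.y / (|x|^2 + |y|^2 - x.y)``

    where *x* describes the candidate compound and *y* is the average
    descriptor vector of reference drug molecules.  The score is symmetric,
    equals 1 exactly when ``x == y`` (nonzero), and is bounded in
    ``[-1/3, 1]``.

    Raises
    ------
    ValueError
        If the vectors differ in length or are both all-zero.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError(f"descriptor vectors must be 1-D and equal length, got {xv.shape} vs {yv.shape}")
    if not (np.isfinite(xv).all() and np.isfinite(yv).all()):
        raise ValueError("descriptor vectors must be finite")
    dot = float(xv @ yv)
    denom = float(xv @ xv) + float(yv @ yv) - dot
    if denom == 0.0:
        raise ValueError("druglikeness undefined: both descriptor vectors are zero")
    return dot / denom


def filter_compounds(
    table: Iterable[CompoundRecord],
    ob_min: float = 30.0,
    dl_min: float = 0.18,
) -> list[CompoundRecord]:
    """Retain compounds with ``OB >= ob_min`` and ``DL >= dl_min``.

    Both comparisons are inclusive; input order is preserved.  The
    defaults are the conventional ADME admission thresholds (OB 30 %,
    DL 0.18).
    """
    records = list(table)
    kept = [r for r in records if r.OB >= ob_min and r.DL >= dl_min]
    logger.info("compound filter OB>=%s DL>=%s: %d/%d retained", ob_min, dl_min, len(kept), len(records))
    return kept


def drop_targetless(
    table: Iterable[CompoundRecord],
    target_map: Mapping[str, Iterable[str]],
) -> tuple[list[CompoundRecord], list[str]]:
    """Remove compounds without any annotated protein target.

    A compound absent from ``target_map`` (or mapped to an empty set) has
    no target and is excluded.  Returns the retained records, in input
    order, and the list of excluded ``mol_id`` values.
    """
    kept: list[CompoundRecord] = []
    excluded: list[str] = []
    for rec in table:
        targets = set(target_map.get(rec.mol_id, ()))
        if targets:
            kept.append(rec)
        else:
            excluded.append(rec.mol_id)
    if excluded:
        logger.info("excluded %d targetless compounds: %s", len(excluded), ", ".join(excluded))
    return kept, excluded


# ---------------------------------------------------------------------------
# TSV interfaces

_COLUMNS = ["mol_id", "name", "herb", "OB", "DL"]


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a compound table TSV with columns mol_id, name, herb, OB, DL."""
    df = pd.read_csv(path, sep="\t", dtype={"mol_id": str, "name": str, "herb": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df.loc[df["OB"].isna() | df["DL"].isna(), "mol_id"].tolist()
    if bad:
        raise ValueError(f"{path}: records with missing OB/DL: {bad}")
    dup = df.loc[df["mol_id"].duplicated(), "mol_id"].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate mol_ids: {dup}")
    return [
        CompoundRecord(r.mol_id, r.name, r.herb, float(r.OB), float(r.DL))
        for r in df.itertuples(index=False)
    ]


def write_compound_table(records: Iterable[CompoundRecord], path: str | Path) -> None:
    df = pd.DataFrame([(r.mol_id, r.name, r.herb, r.OB, r.DL) for r in records], columns=_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_target_map(path: str | Path) -> dict[str, set[str]]:
    """Read a compound->target TSV (columns mol_id, gene) into a dict of sets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"mol_id", "gene"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns mol_id, gene")
    out: dict[str, set[str]] = {}
    for mol_id, gene in zip(df["mol_id"], df["gene"]):
        out.setdefault(mol_id, set())
        if isinstance(gene, str) and gene.strip():
            out[mol_id].add(gene.strip().upper())
    return out


def write_target_map(target_map: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [(m, g) for m in sorted(target_map) for g in sorted(target_map[m])]
    pd.DataFrame(rows, columns=["mol_id", "gene"]).to_csv(path, sep="\t", index=False)
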