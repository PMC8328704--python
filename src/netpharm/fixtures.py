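"""Packaged reference tables.

Three small tables ship with the package and anchor the consistency
checks of the screening logic:

* ``compounds_ar_pn.tsv`` — the 26-row Astragalus Radix / Panax
  notoginseng compound table with OB and DL values (the accompanying
  narrative counts 27 components, but the printed table carries 26 rows;
  the printed rows are what ships);
* ``candidate_targets.tsv`` — the 115-row candidate-target centrality
  table (gene, betweenness, closeness, degree);
* ``docking_scores.tsv`` — the 10-target x 4-component docking-score
  matrix in kcal/mol.

Each loader verifies a frozen SHA-256 before parsing so a corrupted
install fails loudly.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .compounds import CompoundRecord
from .docking import DockingTable

__all__ = [
    "load_compound_table",
    "load_centrality_table",
    "load_docking_table",
]

_CHECKSUMS = {
    "compounds_ar_pn.tsv": "2d7ee0184a7a83a4fd6d8f2c3aef69ba5826b1c97062e0ccc2e245fcada4cb40",
    "candidate_targets.tsv": "cc2c105a08523d6749b2279e630f6599b5b636d9a3bdd5f21b448e44339dbf7c",
    "docking_scores.tsv": "7b6fb2f256e0ae48a9b6a4dee42d352e76d9d5cd12bf2b53acaf49c5aca71852",
}


def _fixture_bytes(name: str) -> bytes:
    data = (resources.files("netpharm") / "data" / name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(f"corrupted install: {name} sha256 {digest} != {_CHECKSUMS[name]}")
    return data


def _fixture_frame(name: str, **kwargs) -> pd.DataFrame:
    from io import BytesIO

    return pd.read_csv(BytesIO(_fixture_bytes(name)), sep="\t", **kwargs)


def load_compound_table() -> list[CompoundRecord]:
    """The packaged herb-pair compound table (26 records)."""
    df = _fixture_frame("compounds_ar_pn.tsv", dtype={"mol_id": str, "name": str, "herb": str})
    return [
        CompoundRecord(r.mol_id, r.name, r.herb, float(r.OB), float(r.DL))
        for r in df.itertuples(index=False)
    ]


def load_centrality_table() -> pd.DataFrame:
    """The packaged 115-row candidate-target centrality table."""
    return _fixture_frame("candidate_targets.tsv")


def load_docking_table() -> DockingTable:
    """The packaged 10x4 docking-score matrix."""
    df = _fixture_frame("docking_scores.tsv", dtype={"target": str, "pdb_id": str})
    components = [c for c in df.columns if c not in ("target", "pdb_id")]
    return DockingTable(
        targets=list(zip(df["target"], df["pdb_id"])),
        components=components,
        scores=df[components].to_numpy(dtype=float),
    )
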