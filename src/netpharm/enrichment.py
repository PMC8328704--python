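"""Over-representation analysis with optional kappa-based term grouping.

A study gene set (e.g. cascade survivors) is tested against annotation
terms by the upper-tail hypergeometric distribution: with a universe of
``N`` genes, a term of size ``K`` and a study set of size ``n`` sharing
``k`` genes, ``p = P(X >= k)`` for ``X ~ Hypergeom(N, K, n)``.  Terms with
``p <= 0.01`` (inclusive) are retained by default.  Redundant terms can be
grouped by Cohen's kappa on their membership indicator vectors with
single linkage, emulating how functional-grouping tools cluster terms.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "hypergeom_ora",
    "kappa_group",
    "cohens_kappa",
    "adjust_p",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
]


def hypergeom_ora(
    study: Iterable[str],
    terms: Mapping[str, Iterable[str]],
    universe: Iterable[str] | None = None,
    p_max: float = 0.01,
    two_sided: bool = False,
    adjust: str = "none",
) -> pd.DataFrame:
    """Hypergeometric over-representation of a study set in each term.

    Parameters
    ----------
    study : gene set
        Genes of interest; genes outside the universe are dropped with a
        warning.
    terms : mapping term -> gene set
        Annotation collection; each term is intersected with the universe.
    universe : gene set, optional
        Background.  Defaults to the union of all term gene sets (the
        choice is logged and should be overridden when a better background
        is known).
    p_max : float
        Inclusive retention threshold on the (raw) p-value.
    two_sided : bool
        If set, report ``min(1, 2 * min(P(X >= k), P(X <= k)))`` instead of
        the enrichment-only upper tail.
    adjust : {"none", "bonferroni", "BH"}
        Multiple-testing correction reported in ``adj_p`` (retention still
        uses the raw p unless callers filter on ``adj_p`` themselves).

    Returns
    -------
    DataFrame sorted ascending by p (ties by term_id) with columns
    term_id, k, K, n, N, p_value, adj_p — rows with ``p <= p_max`` only.
    """
    if universe is None:
        uni = set().union(*(set(g) for g in terms.values())) if terms else set()
        logger.info("ORA universe defaulted to the annotation union: %d genes", len(uni))
    else:
        uni = set(universe)
    if not uni:
        raise ValueError("ORA universe is empty")

    study_set = set(study)
    dropped = study_set - uni
    if dropped:
        logger.warning("%d study genes outside the universe dropped", len(dropped))
    study_set &= uni
    n = len(study_set)
    N = len(uni)

    rows = []
    for term_id in sorted(terms):
        term_genes = set(terms[term_id]) & uni
        K = len(term_genes)
        k = len(term_genes & study_set)
        upper = float(stats.hypergeom.sf(k - 1, N, K, n))
        if two_sided:
            lower = float(stats.hypergeom.cdf(k, N, K, n))
            p = min(1.0, 2.0 * min(upper, lower))
        else:
            p = min(1.0, upper)
        rows.append((term_id, k, K, n, N, p))
    df = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p_value"])
    if len(df):
        df["adj_p"] = adjust_p(df["p_value"].tolist(), method=adjust)
    else:
        df["adj_p"] = pd.Series(dtype=float)
    df = df[df["p_value"] <= p_max]
    df = df.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    logger.info("ORA: %d/%d terms at p <= %g", len(df), len(terms), p_max)
    return df


def cohens_kappa(a: Iterable[str], b: Iterable[str], universe: Iterable[str]) -> float:
    """Cohen's kappa between two gene sets as membership indicators over a universe."""
    uni = set(universe)
    sa, sb = set(a) & uni, set(b) & uni
    N = len(uni)
    if N == 0:
        raise ValueError("empty universe")
    both = len(sa & sb)
    only_a = len(sa - sb)
    only_b = len(sb - sa)
    neither = N - both - only_a - only_b
    po = (both + neither) / N
    pe = ((both + only_a) * (both + only_b) + (only_b + neither) * (only_a + neither)) / N**2
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


def kappa_group(
    rows: pd.DataFrame,
    terms: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    kappa_min: float = 0.4,
) -> pd.DataFrame:
    """Group enriched terms by single-linkage on pairwise Cohen's kappa.

    Terms with kappa >= ``kappa_min`` are linked; connected groups get a
    shared ``group_id`` (numbered by their best p) and the group
    representative is the member with the smallest p (ties: smallest
    term_id).  Returns a copy of ``rows`` with ``group_id`` and
    ``representative`` columns.
    """
    df = rows.copy()
    ids = df["term_id"].tolist()
    missing = [t for t in ids if t not in terms]
    if missing:
        raise ValueError(f"terms absent from the annotation map: {missing}")
    uni = list(universe)

    # union-find single linkage on the kappa graph
    parent = {t: t for t in ids}

    def find(t):
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if cohens_kappa(terms[a], terms[b], uni) >= kappa_min:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra

    groups: dict[str, list[str]] = {}
    for t in ids:
        groups.setdefault(find(t), []).append(t)

    best_p = df.set_index("term_id")["p_value"]
    reps = {}
    group_order = []
    for members in groups.values():
        rep = min(members, key=lambda t: (best_p[t], t))
        group_order.append((best_p[rep], rep, members))
    group_order.sort()
    gid_of = {}
    rep_of = {}
    for gid, (_, rep, members) in enumerate(group_order, start=1):
        for t in members:
            gid_of[t] = gid
            rep_of[t] = rep
    df["group_id"] = [gid_of[t] for t in df["term_id"]]
    df["representative"] = [rep_of[t] for t in df["term_id"]]
    return df


def adjust_p(p_values: Iterable[float], method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment: none, Bonferroni, or Benjamini–Hochberg."""
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "none":
        return p.copy()
    if method.lower() == "bonferroni":
        return multipletests(p, method="bonferroni")[1]
    if method.upper() == "BH":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


# ---------------------------------------------------------------------------
# GMT and gene-list I/O

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: term_id <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = {g.strip().upper() for g in parts[2:] if g.strip()}
    return out


def write_gmt(terms: Mapping[str, Iterable[str]], path: str | Path, descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for term_id in sorted(terms):
            desc = (descriptions or {}).get(term_id, "na")
            genes = "\t".join(sorted(set(terms[term_id])))
            fh.write(f"{term_id}\t{desc}\t{genes}\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip().upper() for line in fh if line.strip()]
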