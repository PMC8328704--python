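"""Differential expression between case and control samples.

Genes are tested on log2-scale expression with Welch's two-sample t-test
(unequal variances) and called up/down by the volcano thresholds
``|log2FC| > 1`` and ``p < 0.05`` — both strict, raw p by default.  An
optional variance-shrinkage variant pulls each per-gene pooled variance
toward the global mean variance for limma-like stabilization at small n.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "test_genes",
    "call_degs",
    "read_expression",
    "write_deg_table",
    "volcano_plot",
]

#: raw intensities are suspected when any value exceeds this; log2(x+1) is applied
RAW_INTENSITY_CUTOFF = 50.0


def _as_matrix(expression: pd.DataFrame, groups: Sequence[str]):
    labels = np.asarray([str(g).lower() for g in groups])
    if len(labels) != expression.shape[1]:
        raise ValueError(
            f"group labels ({len(labels)}) do not match sample columns ({expression.shape[1]})"
        )
    case = labels == "case"
    control = labels == "control"
    unknown = ~(case | control)
    if unknown.any():
        raise ValueError(f"labels must be 'case'/'control', got {set(labels[unknown])}")
    if case.sum() < 2 or control.sum() < 2:
        raise ValueError(
            f"insufficient replication: {case.sum()} case / {control.sum()} control samples (need >= 2 each)"
        )
    return expression.to_numpy(dtype=float), case, control


def test_genes(
    expression: pd.DataFrame,
    groups: Sequence[str],
    shrink: float = 0.0,
    auto_log2: bool = True,
) -> pd.DataFrame:
    """Per-gene log2 fold change and two-sided p-value.

    Parameters
    ----------
    expression : DataFrame
        Genes x samples matrix, log2 scale.  If ``auto_log2`` and any value
        exceeds ``RAW_INTENSITY_CUTOFF`` the matrix is assumed to hold raw
        intensities and ``log2(x + 1)`` is applied (logged loudly).
    groups : sequence of "case"/"control"
        One label per sample column; at least two samples per group.
    shrink : float in [0, 1]
        0 (default) = Welch's t-test with Welch–Satterthwaite df.  A
        positive weight replaces each gene's pooled variance by
        ``(1 - shrink) * s2_gene + shrink * mean(s2)`` and uses a pooled
        two-sample t with ``n1 + n2 - 2`` df — a light-weight analogue of
        moderated-t variance shrinkage.

    Returns
    -------
    DataFrame with columns ``gene``, ``log2fc`` (case minus control),
    ``p_value``.  A gene constant across all samples gets ``p = 1`` by
    convention (logged); a gene with zero variance in both groups but
    different means gets ``p = 0`` (the zero-noise limit).
    """
    if not np.isfinite(expression.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix must be finite")
    x, case, control = _as_matrix(expression, groups)
    if auto_log2 and np.nanmax(x) > RAW_INTENSITY_CUTOFF:
        logger.warning(
            "expression values exceed %.0f: assuming raw intensities, applying log2(x+1)",
            RAW_INTENSITY_CUTOFF,
        )
        x = np.log2(x + 1.0)

    xc, xn = x[:, case], x[:, control]
    n1, n2 = xc.shape[1], xn.shape[1]
    m1, m2 = xc.mean(axis=1), xn.mean(axis=1)
    v1, v2 = xc.var(axis=1, ddof=1), xn.var(axis=1, ddof=1)
    lfc = m1 - m2

    if not 0.0 <= shrink <= 1.0:
        raise ValueError(f"shrink weight must be in [0, 1], got {shrink}")
    if shrink == 0.0:
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(xc, xn, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    else:
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        s2 = (1.0 - shrink) * s2 + shrink * s2.mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            t = lfc / np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n1 + n2 - 2)

    # degenerate variances: constant gene -> p=1; separated constants -> p=0
    # (tolerance absorbs rounding in the variance of numerically identical values)
    eps = np.finfo(float).eps
    tol1 = (8.0 * eps * (1.0 + np.abs(m1))) ** 2
    tol2 = (8.0 * eps * (1.0 + np.abs(m2))) ** 2
    degenerate = (v1 <= tol1) & (v2 <= tol2)
    if degenerate.any():
        zero_diff = np.abs(lfc) <= 8.0 * eps * (1.0 + np.abs(m1) + np.abs(m2))
        n_const = int((degenerate & zero_diff).sum())
        if n_const:
            logger.info("%d genes constant across all samples: p set to 1", n_const)
        lfc = np.where(degenerate & zero_diff, 0.0, lfc)
        p = np.where(degenerate, np.where(zero_diff, 1.0, 0.0), p)
    p = np.nan_to_num(p, nan=1.0)

    return pd.DataFrame({"gene": expression.index.astype(str), "log2fc": lfc, "p_value": p})


def call_degs(
    stats_df: pd.DataFrame,
    lfc_thresh: float = 1.0,
    p_thresh: float = 0.05,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Partition genes into up / down / ns by strict volcano thresholds.

    ``up``: ``log2fc > lfc_thresh`` and ``p < p_thresh``; ``down``:
    ``log2fc < -lfc_thresh`` and ``p < p_thresh``; otherwise ``ns``.  Both
    inequalities are strict.  BH-adjusted p-values are always reported in
    ``adj_p``; they drive the call only when ``use_adjusted``.
    """
    df = stats_df.copy()
    if len(df):
        df["adj_p"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
        p = df["adj_p"] if use_adjusted else df["p_value"]
        df["call"] = np.select(
            [(df["log2fc"] > lfc_thresh) & (p < p_thresh), (df["log2fc"] < -lfc_thresh) & (p < p_thresh)],
            ["up", "down"],
            default="ns",
        )
    else:
        df["adj_p"] = pd.Series(dtype=float)
        df["call"] = pd.Series(dtype=str)
    counts = df["call"].value_counts()
    logger.info(
        "DEG call |log2FC|>%s, p<%s: %d up, %d down, %d ns",
        lfc_thresh, p_thresh, counts.get("up", 0), counts.get("down", 0), counts.get("ns", 0),
    )
    return df


# ---------------------------------------------------------------------------
# I/O and plotting

def read_expression(expr_path: str | Path, labels_path: str | Path):
    """Read a genes x samples TSV and a (sample, group) labels TSV.

    Returns ``(expression DataFrame, list of group labels)`` with label
    order matched to the expression columns.
    """
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    lab = pd.read_csv(labels_path, sep="\t", dtype=str)
    if not {"sample", "group"}.issubset(lab.columns):
        raise ValueError(f"{labels_path}: expected columns sample, group")
    mapping = dict(zip(lab["sample"], lab["group"]))
    missing = [s for s in expr.columns if s not in mapping]
    if missing:
        raise ValueError(f"samples without group label: {missing}")
    return expr, [mapping[s] for s in expr.columns]


def write_deg_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def volcano_plot(df: pd.DataFrame, path: str | Path) -> None:
    """Volcano plot: log2FC vs -log10 p, up in red, down in blue, ns in black."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"up": "red", "down": "blue", "ns": "black"}
    fig, ax = plt.subplots(figsize=(5, 4))
    neglogp = -np.log10(np.clip(df["p_value"].to_numpy(), 1e-300, None))
    for call, color in colors.items():
        m = df["call"] == call
        ax.scatter(df.loc[m, "log2fc"], neglogp[m.to_numpy()], s=4, c=color, label=call)
    ax.axhline(-np.log10(0.05), ls="--", lw=0.5, c="gray")
    for x in (-1, 1):
        ax.axvline(x, ls="--", lw=0.5, c="gray")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
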