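"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the screening pipeline is testable without a database
download: this module generates a case/control expression matrix with
planted differential genes, a scale-free background interactome with
planted hubs, a compound table with oral-bioavailability/druglikeness
spread and partially empty target maps, and a term-annotation collection
with planted enriched terms — together with the ground truth for each.

The default two-group design is 9 cases vs 13 controls, matching the
glomerular microarray comparison the pipeline was built around (so that,
e.g., tie-free AUCs move on a 1/117 grid).  Baseline log2 expression
means are drawn normal(7, 2), mimicking microarray intensity spread.

All draws come from one :class:`numpy.random.Generator` seeded once per
bundle; the sub-generators are invoked in a fixed, documented order
(expression, interactome, compounds, annotations) so earlier outputs are
stable if later generators change.  Each generator is also callable with
its own seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .compounds import CompoundRecord, write_compound_table, write_target_map
from .enrichment import write_gmt
from .interactome import write_edgelist, write_sif

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SyntheticBundle",
    "gen_expression",
    "gen_interactome",
    "gen_compounds",
    "gen_annotations",
    "gen_bundle",
    "write_bundle",
]

#: baseline per-gene mean distribution on the log2 scale (microarray-like spread)
BASELINE_MEAN = 7.0
BASELINE_SD = 2.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic study bundle.

    Counts are positive; ``lfc_range`` lies strictly above 1 so every
    planted differential gene clears the ``|log2FC| > 1`` calling
    threshold by construction; group sizes default to the 9-vs-13 design.
    """

    seed: int = 0
    n_genes: int = 2000
    n_case: int = 9
    n_control: int = 13
    n_deg: int = 200
    lfc_range: tuple[float, float] = (1.5, 3.0)
    noise_sd: float = 0.5
    interactome_nodes: int = 500
    attachment_m: int = 3
    n_hubs: int = 10
    hub_degree: int = 50
    n_compounds: int = 27
    fraction_targetless: float = 5.0 / 27.0
    targets_per_compound_mean: float = 8.0
    target_pool_size: int = 200
    n_terms: int = 50
    term_size_range: tuple[int, int] = (20, 80)
    n_planted_terms: int = 3
    planted_term_overlap: float = 0.5

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_case": self.n_case,
            "n_control": self.n_control,
            "n_deg": self.n_deg,
            "interactome_nodes": self.interactome_nodes,
            "attachment_m": self.attachment_m,
            "n_compounds": self.n_compounds,
            "n_terms": self.n_terms,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.n_deg > self.n_genes:
            raise ValueError(f"n_deg ({self.n_deg}) exceeds n_genes ({self.n_genes})")
        if self.n_case + self.n_control < 4:
            raise ValueError("need n_case + n_control >= 4")
        lo, hi = self.lfc_range
        if not (1.0 < lo <= hi):
            raise ValueError(f"lfc_range must satisfy 1 < lo <= hi, got {self.lfc_range}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.interactome_nodes <= self.attachment_m:
            raise ValueError("interactome_nodes must exceed attachment_m")
        if not 0.0 <= self.fraction_targetless <= 1.0:
            raise ValueError("fraction_targetless must be in [0, 1]")
        if not 0.0 <= self.planted_term_overlap <= 1.0:
            raise ValueError("planted_term_overlap must be in [0, 1]")
        tlo, thi = self.term_size_range
        if not (0 < tlo <= thi <= self.n_genes):
            raise ValueError(f"term_size_range must be within the gene universe, got {self.term_size_range}")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class SyntheticBundle:
    """All pipeline inputs plus the planted ground truth."""

    config: SimConfig
    expression: pd.DataFrame  # genes x samples, log2 scale
    group_labels: list[str]
    interactome: nx.Graph
    compound_table: list[CompoundRecord]
    compound_targets: dict[str, set[str]]
    annotations: dict[str, set[str]]
    truth: dict = field(default_factory=dict)  # degs: {gene: lfc}, hubs: set, enriched_terms: set


def _rng(config: SimConfig, seed: int | None, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(config.seed if seed is None else seed)


def gen_expression(
    config: SimConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Case/control log2 expression with planted differential genes.

    Baseline per-gene means are normal(7, 2) on the log2 scale; ``n_deg``
    randomly chosen genes are shifted in cases by a signed log2 effect
    drawn uniformly from ``lfc_range`` (random sign), and i.i.d. normal
    noise with ``noise_sd`` is added everywhere.  Deterministic given the
    seed.

    Returns ``(expression DataFrame, group labels, {gene: planted lfc})``.
    """
    r = _rng(config, seed, rng)
    genes = config.gene_ids()
    n_samples = config.n_case + config.n_control
    labels = ["case"] * config.n_case + ["control"] * config.n_control
    samples = [f"case_{i+1}" for i in range(config.n_case)] + [
        f"control_{i+1}" for i in range(config.n_control)
    ]

    baseline = r.normal(BASELINE_MEAN, BASELINE_SD, size=config.n_genes)
    deg_idx = r.choice(config.n_genes, size=config.n_deg, replace=False)
    lfc = r.uniform(config.lfc_range[0], config.lfc_range[1], size=config.n_deg)
    lfc *= r.choice([-1.0, 1.0], size=config.n_deg)

    x = np.tile(baseline[:, None], (1, n_samples))
    x[deg_idx, : config.n_case] += lfc[:, None]
    x += r.normal(0.0, config.noise_sd, size=x.shape)

    expr = pd.DataFrame(x, index=genes, columns=samples)
    planted = {genes[i]: float(e) for i, e in zip(deg_idx, lfc)}
    logger.info("gen_expression: %d genes, %d+%d samples, %d planted DEGs", config.n_genes, config.n_case, config.n_control, config.n_deg)
    return expr, labels, planted


def gen_interactome(
    config: SimConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[nx.Graph, set[str]]:
    """Scale-free background interactome with explicitly planted hubs.

    A Barabási–Albert preferential-attachment graph on the first
    ``interactome_nodes`` gene ids is augmented by ``n_hubs`` planted
    hubs: randomly chosen nodes receive degree-proportional extra edges
    until their degree reaches ``hub_degree`` (preferential wiring keeps
    hub neighborhoods realistically rich in other well-connected nodes).
    The result is simple and undirected, and every planted hub has degree
    strictly above twice the median degree.

    Returns ``(graph, planted hub set)``.
    """
    r = _rng(config, seed, rng)
    genes = config.gene_ids()[: config.interactome_nodes]
    ba_seed = int(r.integers(0, 2**31 - 1))
    g0 = nx.barabasi_albert_graph(config.interactome_nodes, config.attachment_m, seed=ba_seed)
    g = nx.relabel_nodes(g0, dict(enumerate(genes)))

    hubs: set[str] = set()
    if config.n_hubs > 0:
        hub_nodes = r.choice(config.interactome_nodes, size=config.n_hubs, replace=False)
        hubs = {genes[i] for i in hub_nodes}
        nodes = np.array(genes)
        for h in sorted(hubs):
            while g.degree(h) < config.hub_degree:
                deg = np.array([g.degree(v) for v in nodes], dtype=float)
                # degree-proportional choice among non-neighbors
                deg[[i for i, v in enumerate(nodes) if v == h or g.has_edge(h, v)]] = 0.0
                total = deg.sum()
                if total == 0:
                    break
                target = r.choice(nodes, p=deg / total)
                g.add_edge(h, str(target))

    degrees = sorted(d for _, d in g.degree())
    median = float(np.median(degrees))
    low = [h for h in hubs if g.degree(h) <= 2 * median]
    if low:  # should not happen with default hub_degree >> median
        logger.warning("planted hubs at or below 2x median degree: %s", low)
    logger.info("gen_interactome: %d nodes, %d edges, %d planted hubs, median degree %.1f", g.number_of_nodes(), g.number_of_edges(), len(hubs), median)
    return g, hubs


def gen_compounds(
    config: SimConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[CompoundRecord], dict[str, set[str]]]:
    """Compound table with OB/DL spread and a partially empty target map.

    OB is uniform on [10, 110] (both sides of the 30 % threshold), DL
    uniform on [0.05, 0.95] (both sides of 0.18).  A ``fraction_targetless``
    share of compounds gets an empty target set; the rest draw
    ``1 + Poisson(mean - 1)`` targets from a shared pool of interactome
    genes, so target sets overlap across compounds.
    """
    r = _rng(config, seed, rng)
    pool = config.gene_ids()[: min(config.target_pool_size, config.interactome_nodes)]
    n_targetless = int(round(config.fraction_targetless * config.n_compounds))
    targetless = set(r.choice(config.n_compounds, size=n_targetless, replace=False).tolist())

    records: list[CompoundRecord] = []
    target_map: dict[str, set[str]] = {}
    for i in range(config.n_compounds):
        mol_id = f"CMP{i+1:04d}"
        herb = "AR" if r.random() < 0.7 else "PN"
        ob = float(r.uniform(10.0, 110.0))
        dl = float(r.uniform(0.05, 0.95))
        records.append(CompoundRecord(mol_id, f"compound-{i+1}", herb, ob, dl))
        if i in targetless:
            target_map[mol_id] = set()
        else:
            k = 1 + int(r.poisson(max(config.targets_per_compound_mean - 1.0, 0.0)))
            k = min(k, len(pool))
            target_map[mol_id] = set(r.choice(pool, size=k, replace=False).tolist())
    logger.info("gen_compounds: %d compounds, %d targetless", config.n_compounds, n_targetless)
    return records, target_map


def gen_annotations(
    config: SimConfig,
    planted_genes: Iterable[str] = (),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, set[str]], set[str]]:
    """Term -> gene-set annotation map with planted enriched terms.

    ``n_planted_terms`` terms draw a ``planted_term_overlap`` fraction of
    their members from ``planted_genes`` (typically the planted DEG or hub
    truth) and the rest from the remaining universe; all other terms are
    uniform draws from the universe.

    Returns ``(annotations, planted term ids)``.
    """
    r = _rng(config, seed, rng)
    universe = config.gene_ids()
    planted_pool = [g for g in planted_genes if g in set(universe)]
    other_pool = [g for g in universe if g not in set(planted_pool)]

    annotations: dict[str, set[str]] = {}
    planted_terms: set[str] = set()
    lo, hi = config.term_size_range
    n_planted = min(config.n_planted_terms, config.n_terms) if planted_pool else 0
    for t in range(config.n_terms):
        term_id = f"TERM{t+1:04d}"
        size = int(r.integers(lo, hi + 1))
        if t < n_planted:
            k_planted = min(int(round(config.planted_term_overlap * size)), len(planted_pool))
            members = set(r.choice(planted_pool, size=k_planted, replace=False).tolist())
            rest = r.choice(other_pool, size=size - k_planted, replace=False)
            members.update(rest.tolist())
            planted_terms.add(term_id)
        else:
            members = set(r.choice(universe, size=size, replace=False).tolist())
        annotations[term_id] = members
    logger.info("gen_annotations: %d terms, %d planted", config.n_terms, len(planted_terms))
    return annotations, planted_terms


def gen_bundle(config: SimConfig) -> SyntheticBundle:
    """Generate all inputs from one seeded stream in a fixed order.

    Order: expression, interactome, compounds, annotations.  Identical
    configs (including the seed) give bit-identical bundles.
    """
    r = np.random.default_rng(config.seed)
    expression, labels, planted_degs = gen_expression(config, rng=r)
    graph, hubs = gen_interactome(config, rng=r)
    records, target_map = gen_compounds(config, rng=r)
    annotations, planted_terms = gen_annotations(config, planted_genes=sorted(planted_degs), rng=r)
    return SyntheticBundle(
        config=config,
        expression=expression,
        group_labels=labels,
        interactome=graph,
        compound_table=records,
        compound_targets=target_map,
        annotations=annotations,
        truth={"degs": planted_degs, "hubs": hubs, "enriched_terms": planted_terms},
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every bundle component to TSV/SIF/GMT files in ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "labels": out / "labels.tsv",
        "interactome_sif": out / "interactome.sif",
        "interactome_edges": out / "interactome_edges.tsv",
        "compounds": out / "compounds.tsv",
        "compound_targets": out / "compound_targets.tsv",
        "annotations": out / "annotations.gmt",
        "truth_degs": out / "truth_degs.tsv",
        "truth_hubs": out / "truth_hubs.txt",
        "truth_terms": out / "truth_terms.txt",
    }
    bundle.expression.to_csv(paths["expression"], sep="\t", index_label="gene")
    pd.DataFrame(
        {"sample": bundle.expression.columns, "group": bundle.group_labels}
    ).to_csv(paths["labels"], sep="\t", index=False)
    write_sif(bundle.interactome, paths["interactome_sif"])
    write_edgelist(bundle.interactome, paths["interactome_edges"])
    write_compound_table(bundle.compound_table, paths["compounds"])
    write_target_map(bundle.compound_targets, paths["compound_targets"])
    write_gmt(bundle.annotations, paths["annotations"])
    pd.DataFrame(
        sorted(bundle.truth["degs"].items()), columns=["gene", "lfc"]
    ).to_csv(paths["truth_degs"], sep="\t", index=False)
    paths["truth_hubs"].write_text("\n".join(sorted(bundle.truth["hubs"])) + "\n")
    paths["truth_terms"].write_text("\n".join(sorted(bundle.truth["enriched_terms"])) + "\n")
    return paths
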