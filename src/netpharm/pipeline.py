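"""End-to-end orchestration of the screening workflow.

Stages run in the canonical order: compound screening -> putative-target
collection -> DEG calling -> seed-expanded networks -> edge-intersection
merge -> two-stage centrality cascade -> enrichment of survivors -> ROC
validation -> docking-score summary (optional).  Every stage reads and
writes plain files, logs its input/output counts and the thresholds it
applied, and contributes to a run manifest, so a rerun with the same
config and inputs yields an identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

import pandas as pd

from . import compounds as cmod
from . import diffexpr as dmod
from . import docking as kmod
from . import enrichment as emod
from . import interactome as imod
from . import roc as rmod
from . import topology as tmod

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, message: str, manifest: dict):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class RunConfig:
    """All inputs, thresholds and flags of one pipeline run."""

    # input paths
    compounds: str = ""
    compound_targets: str = ""
    expression: str = ""
    labels: str = ""
    interactome: str = ""
    annotations: str = ""
    docking: str = ""  # optional
    outdir: str = "netpharm_run"
    # thresholds
    ob_min: float = 30.0
    dl_min: float = 0.18
    lfc_thresh: float = 1.0
    p_deg: float = 0.05
    p_enrich: float = 0.01
    kappa_min: float = 0.4
    # flags
    cascade_recompute: bool = True
    include_neighbor_edges: bool = True
    bc_divisor: str = "pairs"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_deg <= 1 or not 0 <= self.p_enrich <= 1:
            raise ValueError("p thresholds must lie in [0, 1]")
        if self.ob_min < 0 or not 0 <= self.dl_min <= 1:
            raise ValueError("ob_min must be >= 0 and dl_min in [0, 1]")
        if self.lfc_thresh < 0 or not -1 <= self.kappa_min <= 1:
            raise ValueError("lfc_thresh must be >= 0 and kappa_min in [-1, 1]")

    # flat key=value config file, round-trips losslessly
    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key, value in asdict(self).items():
                fh.write(f"{key}={value}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                key, value = line.split("=", 1)
                key = key.strip()
                value = value.strip()
                if key not in types:
                    raise ValueError(f"unknown config key {key!r}")
                t = types[key]
                if t == "bool":
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                elif t == "int":
                    kwargs[key] = int(value)
                elif t == "float":
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return (and write) the run manifest.

    The manifest records, per stage, the input and output row counts, the
    thresholds actually applied, elapsed time, and a checksum for every
    file written.  A failing stage aborts with :class:`PipelineError`
    carrying the partial manifest; a degenerate-but-valid outcome (e.g. an
    empty merged network) halts cleanly with an explanatory status.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "status": "ok"}
    t_start = time.time()

    def record(stage: str, info: dict, files: dict[str, Path] = {}) -> None:
        info = dict(info)
        info["files"] = {k: {"path": str(p), "sha256": _sha256(p)} for k, p in files.items()}
        info["elapsed_s"] = round(time.time() - t_start, 3)
        manifest["stages"][stage] = info
        logger.info("stage %s: %s", stage, {k: v for k, v in info.items() if k != "files"})

    def finish(status: str) -> dict:
        manifest["status"] = status
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return manifest

    try:
        # -- compound screening ------------------------------------------------
        stage = "screen"
        records = cmod.read_compound_table(config.compounds)
        target_map = cmod.read_target_map(config.compound_targets)
        admitted = cmod.filter_compounds(records, ob_min=config.ob_min, dl_min=config.dl_min)
        kept, excluded = cmod.drop_targetless(admitted, target_map)
        seeds_targets = sorted(set().union(*(target_map[r.mol_id] for r in kept)) if kept else set())
        screened_path = out / "compounds_screened.tsv"
        cmod.write_compound_table(kept, screened_path)
        report_path = out / "compounds_excluded.tsv"
        pd.DataFrame(
            [(m, "no-target") for m in excluded], columns=["mol_id", "reason"]
        ).to_csv(report_path, sep="\t", index=False)
        targets_path = out / "putative_targets.txt"
        targets_path.write_text("\n".join(seeds_targets) + ("\n" if seeds_targets else ""))
        record(stage, {
            "input_compounds": len(records),
            "admitted_ob_dl": len(admitted),
            "retained": len(kept),
            "excluded_targetless": len(excluded),
            "putative_targets": len(seeds_targets),
            "thresholds": {"ob_min": config.ob_min, "dl_min": config.dl_min},
        }, {"screened": screened_path, "excluded": report_path, "targets": targets_path})

        # -- differential expression ------------------------------------------
        stage = "deg"
        expr, groups = dmod.read_expression(config.expression, config.labels)
        stats = dmod.test_genes(expr, groups)
        degs = dmod.call_degs(stats, lfc_thresh=config.lfc_thresh, p_thresh=config.p_deg)
        deg_path = out / "deg_table.tsv"
        dmod.write_deg_table(degs, deg_path)
        deg_genes = sorted(degs.loc[degs["call"] != "ns", "gene"])
        counts = degs["call"].value_counts()
        record(stage, {
            "genes": len(degs),
            "up": int(counts.get("up", 0)),
            "down": int(counts.get("down", 0)),
            "ns": int(counts.get("ns", 0)),
            "thresholds": {"lfc": config.lfc_thresh, "p": config.p_deg},
        }, {"deg_table": deg_path})

        # -- networks and merge ------------------------------------------------
        stage = "net"
        background = (
            imod.read_sif(config.interactome)
            if str(config.interactome).endswith(".sif")
            else imod.read_edgelist(config.interactome)
        )
        net_targets = imod.expand_seeds(seeds_targets, background, config.include_neighbor_edges)
        net_degs = imod.expand_seeds(deg_genes, background, config.include_neighbor_edges)
        merged = imod.merge_intersection(net_targets, net_degs)
        merged_path = out / "merged_network.sif"
        imod.write_sif(merged, merged_path)
        record(stage, {
            "background": imod.network_stats(background),
            "target_network": imod.network_stats(net_targets),
            "deg_network": imod.network_stats(net_degs),
            "merged": imod.network_stats(merged),
        }, {"merged": merged_path})
        if merged.number_of_nodes() == 0:
            return finish("halted: merged network is empty")

        # -- centrality cascade ------------------------------------------------
        stage = "cascade"
        result = tmod.cascade_screen(
            merged, recompute=config.cascade_recompute, divisor=config.bc_divisor
        )
        surv_path = out / "cascade_survivors.tsv"
        tmod.write_centrality_table(result.survivor_table, surv_path)
        thr_path = out / "cascade_thresholds.tsv"
        pd.DataFrame(
            [
                ("stage1_degree", result.stage1_threshold),
                *[(f"stage2_{k}", v) for k, v in result.stage2_thresholds.items()],
            ],
            columns=["threshold", "value"],
        ).to_csv(thr_path, sep="\t", index=False)
        stage1_path = out / "stage1_network.sif"
        stage2_path = out / "stage2_network.sif"
        imod.write_sif(result.stage1_network, stage1_path)
        imod.write_sif(result.stage2_network, stage2_path)
        record(stage, {
            "stage1_nodes": result.stage1_network.number_of_nodes(),
            "stage2_nodes": result.stage2_network.number_of_nodes(),
            "stage1_threshold": result.stage1_threshold,
            "stage2_thresholds": result.stage2_thresholds,
            "cascade_status": result.status,
            "recompute": config.cascade_recompute,
        }, {"survivors": surv_path, "thresholds": thr_path, "stage1": stage1_path, "stage2": stage2_path})
        if not result.survivors:
            return finish(f"halted: {result.status}")

        # -- enrichment ---------------------------------------------------------
        stage = "enrich"
        terms = emod.read_gmt(config.annotations)
        enriched = emod.hypergeom_ora(result.survivors, terms, p_max=config.p_enrich, adjust="BH")
        if len(enriched) > 1:
            universe = set().union(*terms.values())
            enriched = emod.kappa_group(enriched, terms, universe, kappa_min=config.kappa_min)
        enrich_path = out / "enrichment.tsv"
        enriched.to_csv(enrich_path, sep="\t", index=False)
        record(stage, {
            "terms_tested": len(terms),
            "terms_enriched": len(enriched),
            "thresholds": {"p_enrich": config.p_enrich, "kappa_min": config.kappa_min},
        }, {"enrichment": enrich_path})

        # -- ROC validation ------------------------------------------------------
        stage = "roc"
        hub_genes = [g for g in result.survivors if g in set(expr.index.astype(str))]
        roc_df, _ = rmod.roc_table(expr, groups, genes=hub_genes)
        roc_path = out / "roc_table.tsv"
        roc_df.to_csv(roc_path, sep="\t", index=False)
        record(stage, {
            "genes_tested": len(roc_df),
            "significant": int((roc_df["p_value"] < 0.05).sum()) if len(roc_df) else 0,
        }, {"roc": roc_path})

        # -- docking summary (optional) ------------------------------------------
        if config.docking:
            stage = "dock"
            table = kmod.read_docking_table(config.docking)
            summary = kmod.best_per_target(table)
            extremes = kmod.global_extremes(table)
            dock_path = out / "docking_summary.tsv"
            summary.to_csv(dock_path, sep="\t", index=False)
            record(stage, {
                "targets": len(table.targets),
                "components": len(table.components),
                "global_min": extremes["min"],
                "global_max": extremes["max"],
            }, {"summary": dock_path})

    except PipelineError:
        raise
    except Exception as exc:  # abort with stage-named error + partial manifest
        finish(f"failed at {stage}")
        raise PipelineError(stage, str(exc), manifest) from exc

    return finish("ok")
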