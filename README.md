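# netpharm

A network-pharmacology screening pipeline for herb-pair compound analysis:
given a table of herbal ingredients, a case/control expression study and a
background protein–protein interaction (PPI) network, it nominates core
therapeutic targets by ADME compound screening, differential-expression
calling, intersection of seed-expanded PPI networks, a two-stage
centrality screening cascade, over-representation analysis, docking-score
summaries and ROC validation. It was built around the Astragalus Radix –
Panax notoginseng herb pair studied against diabetic nephropathy (a
9-case vs 13-control glomerular microarray design), but every stage is a
generic, parameterized operation.

The package ships a synthetic-data generator that plants known
differential genes, network hubs and enriched annotation terms, so the
entire pipeline is testable end to end without any database access.

## The method

1. **ADME screening** — ingredients are admitted when oral
   bioavailability `OB >= 30 %` and druglikeness `DL >= 0.18` (both
   inclusive). DL is the Tanimoto score between a compound's molecular
   descriptor vector *x* and the average drug descriptor vector *y*:
   `DL(x, y) = x·y / (‖x‖² + ‖y‖² − x·y)`. Compounds without any
   annotated protein target are then excluded.
2. **DEG calling** — per-gene Welch *t* on log2 expression; genes with
   `|log2FC| > 1` and `p < 0.05` (both strict) are called up/down.
3. **Network construction** — the putative-target set and the DEG set
   are each expanded in the background interactome to seeds + first
   neighbors with all induced edges; the two networks are merged by
   **edge intersection** (nodes = endpoints of surviving edges).
4. **Centrality cascade** — degree (DC), betweenness (BC, Brandes) and
   closeness (CC) centralities are computed from first principles.
   Stage 1 keeps nodes with `DC > 2 × median(DC)`; stage 2 recomputes
   DC/BC/CC on the stage-1 subgraph and keeps nodes strictly above all
   three medians. Survivors are the candidate core targets.
5. **Enrichment** — upper-tail hypergeometric over-representation of the
   survivors in GMT annotation terms, retained at `p <= 0.01`, with
   optional Cohen's-kappa single-linkage grouping of redundant terms.
6. **Docking summary** — per-target best binding energies and affinity
   classes from precomputed docking tables (strong < −7, good < −5,
   binding < −4.25 kcal/mol; boundaries fall to the weaker class).
7. **ROC validation** — per-gene AUC by the rank (Mann–Whitney)
   formulation with tie handling and automatic orientation; with 9 vs 13
   samples and no ties every AUC is a multiple of 1/117.

## Worked example

Generate a synthetic study and run the whole workflow:

```sh
netpharm simulate --seed 1 --outdir sim
python - <<'EOF'
from netpharm.pipeline import RunConfig
RunConfig(
    compounds="sim/compounds.tsv", compound_targets="sim/compound_targets.tsv",
    expression="sim/expression.tsv", labels="sim/labels.tsv",
    interactome="sim/interactome.sif", annotations="sim/annotations.gmt",
    outdir="run",
).to_file("run.conf")
EOF
netpharm run-all --config run.conf
```

prints `status: ok; manifest in run/manifest.json`, and the manifest
records per stage (seed 1):

- `screen` — 27 input compounds, 15 pass OB/DL, 14 keep a target set,
  yielding 90 putative targets;
- `deg` — 2000 genes: 91 up, 109 down (the generator planted 200);
- `net` — 500-node background; target network 448 nodes / 1746 edges,
  DEG network 271 / 997, merged intersection 248 nodes / 920 edges;
- `cascade` — stage 1 keeps 51 nodes (`DC > 8`), stage 2 keeps 22
  survivors, which include all 10 planted hubs;
- `roc` — 22 survivors tested for case/control discrimination.

Summarizing the packaged docking table:

```sh
netpharm dock --scores src/netpharm/data/docking_scores.tsv --out dock.tsv
# global min -9.7 at [('JUN', 'Kaempferol'), ('JUN', 'Isorhamnetin')], max -6.0
```

`dock.tsv` then begins

```text
target  pdb_id  best_score  best_components                    affinity_class
MAPK1   4iz5    -8.4        Quercetin,Kaempferol,Isorhamnetin  strong
AKT1    1unq    -6.6        Formononetin                       good
```

i.e. MAPK1's strongest predicted binding is −8.4 kcal/mol, tied across
three flavonoids, in the "strong" affinity class (< −7).

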