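# Methods

## Scope and model

The pipeline operationalizes a common network-pharmacology design: herbal
ingredients are filtered by pharmacokinetic admissibility, their protein
targets and a disease's differential genes are projected into a background
interactome, and the intersection of the two neighborhoods is screened for
topologically central "core" targets, which are then annotated
(enrichment), prioritized (docking-score summaries) and validated as
markers (ROC). The package implements each stage as a pure function over
plain files and data frames; the `pipeline` module composes them and
records a manifest so runs are auditable and reproducible.

Live database queries (compound databases, interaction databases, GEO,
GO/KEGG), docking execution and network visualization are deliberately
out of scope; published tables and precomputed score matrices are
consumed as data, and a synthetic generator supplies statistically
realistic stand-ins for everything else.

## Compound screening

Druglikeness is the Tanimoto score
`DL(x, y) = x·y / (‖x‖² + ‖y‖² − x·y)` between a compound descriptor
vector and the average drug descriptor vector. Because the descriptor
sets behind published DL columns are not recoverable, the packaged
26-row compound table is consumed as data and the score is offered for
caller-supplied vectors. Admission uses inclusive thresholds
`OB >= 30 %`, `DL >= 0.18`: the table itself contains a compound with DL
exactly 0.18, which the source screening retained, fixing the
inclusive reading. (The narrative around that table counts 27
components while the printed table has 26 rows; the printed rows are
shipped and the mismatch is simply noted here rather than guessed at.)
Compounds with an empty target set are removed afterwards; both filters
commute and are idempotent.

## Differential expression

Welch's two-sample t-test on log2 intensities stands in for a moderated
linear-model fit: with the calling thresholds being the specified
computation (`|log2FC| > 1` and `p < 0.05`, both strict, raw p), the test
engine only needs to be calibrated, which the acceptance study verifies
(type-I error 0.05 ± 0.01 on null data in the 9v13 design). An optional
`shrink` weight pulls per-gene pooled variances toward the global mean
variance, a lightweight analogue of empirical-Bayes moderation for users
who want extra stability at small n. BH-adjusted p-values are always
reported but drive the call only on request, matching the literal "P <
0.05" reading. Degenerate genes are handled by convention: constant
across all samples → p = 1; zero within-group variance with distinct
means (the zero-noise limit) → p = 0. Both conventions use a
floating-point tolerance of `8·eps·(1+|mean|)` on the standard deviation
scale so that numerically identical values are treated as identical.
Matrices with values above 50 are assumed to be raw intensities and are
log2(x+1)-transformed with a loud warning.

## Networks and the cascade

Seed expansion takes seeds plus first neighbors with **all induced
edges** by default; the stricter seed-incident-edges variant is a flag.
The induced-edge default reflects how interactome browsers expand seed
lists (a few hundred seeds typically explode to thousands of nodes).
Merging is defined on **edges** — the natural reading of intersecting
"interaction data" — with node intersection available as a sensitivity
switch; the edge law `E(a∩b) = E(a) ∩ E(b)` is asserted exactly in tests,
along with commutativity, associativity and idempotence.

Centralities are computed from first principles: degree as incident edge
count; betweenness by Brandes' dependency accumulation over BFS
shortest-path DAGs; closeness as `(n_c − 1) / Σ d(v,u)` within the node's
component (isolated nodes → 0). Betweenness is normalized per connected
component by `(n_c−1)(n_c−2)/2`; published tables do not always reveal
whether the divisor was halved, so `divisor="ordered"` selects
`(n_c−1)(n_c−2)` instead. The implementation is verified against an
independent path-counting oracle (Floyd–Warshall distances plus
adjacency-power path counts) on every non-isomorphic graph up to 7 nodes,
exhaustive labeled connected 4-node graphs, and random graphs up to 30
nodes, and cross-checked against networkx.

The cascade uses strict inequalities at both stages ("more than twice
the median", "more than the median values"): stage 1 keeps
`DC > 2·median(DC)` over the merged network; stage 2 recomputes DC/BC/CC
on the stage-1 induced subgraph (the per-network behavior of interactive
centrality tools) and keeps nodes above all three medians. Recomputation
is the default and `recompute=False` reuses merged-network values, since
either convention is defensible; the choice is logged in the manifest.
The median of an even-length sample is the mean of the two central order
statistics. Degenerate cascades (e.g. regular graphs, where no degree
exceeds twice the median) return an empty result with an explanatory
status instead of raising.

## Enrichment

Over-representation uses the upper-tail hypergeometric
`p = P(X >= k)` for a term of size K, study of size n, universe N —
enrichment-only by default, two-sided optional. Retention is inclusive
at `p <= 0.01`. The universe defaults to the union of the annotation
collection (logged, overridable) because no background is otherwise
specified. Term redundancy is grouped by Cohen's kappa between
membership indicator vectors with single linkage at kappa ≥ 0.4 — an
emulation of how functional-grouping tools cluster terms, not a claim of
equivalence. Bonferroni and BH corrections are available; raw p drives
retention by default since the stated threshold does not name a
correction.

## ROC validation

AUC is the rank (Mann–Whitney) statistic `U/(n₁·n₂)` with midranks, so
tied pairs count ½, and the reported AUC is `max(AUC, 1 − AUC)` with the
orientation recorded — published AUC panels report all values ≥ 0.5
without stating direction. Significance is the two-sided
normal-approximated Mann–Whitney test with tie and continuity
corrections (`p_method="exact"` switches to the exact distribution,
suited to groups ≤ 12 without ties). The tie-aware curve is built by
sweeping distinct thresholds; its trapezoidal area equals the rank AUC
exactly, which the tests assert. With the default 9-vs-13 design a
tie-free AUC lives on a 1/117 grid; the six significant published AUCs
of the motivating study are verified to be 109, 114, 108, 101, 93 and
97 over 117.

## Docking summaries

Binding-energy tables (kcal/mol, more negative = stronger) are
summarized to per-target minima with all tied ligands listed, global
extremes with their cells, and affinity classes at strict cutoffs −7 /
−5 / −4.25 ("less than" is strict, so −5.0 exactly is "binding", the
weaker class). The motivating study's prose cites a "lowest energy value
at 9.7 kcal/mol" for one target; its own table prints −9.7, and the sign
typo is resolved in favor of the table. The prose also names a different
third ligand in one tie than the table's row implies; again the printed
matrix wins.

## Synthetic data

The generator emulates the study conditions the pipeline assumes:

- **Expression** — genes × (9 case + 13 control) samples on the log2
  scale; baseline per-gene means ~ Normal(7, 2) (microarray-like
  intensity spread), i.i.d. Normal(0, noise_sd) noise with
  `noise_sd = 0.5` by default, and `n_deg = 200` of `n_genes = 2000`
  genes shifted in cases by a signed uniform effect from
  `lfc_range = (1.5, 3)` — strictly above the |log2FC| > 1 calling
  threshold, so planted truth is recoverable by construction.
- **Interactome** — Barabási–Albert preferential attachment
  (500 nodes, m = 3) plus 10 planted hubs wired degree-proportionally up
  to degree 50 — an order of magnitude above the background median, the
  regime the cascade is meant to detect, and preferential wiring keeps
  hub neighborhoods realistically rich in other well-connected nodes.
- **Compounds** — 27 compounds, OB ~ U(10, 110) and DL ~ U(0.05, 0.95)
  spanning both admission thresholds; a 5/27 fraction is targetless to
  exercise the exclusion rule; target sets draw 1 + Poisson(7) genes
  from a shared 200-gene pool so compounds share targets.
- **Annotations** — 50 terms of size 20–80; 3 planted terms draw half
  their members (`planted_term_overlap = 0.5`) from the planted DEG set.

One `numpy` Generator is seeded per bundle and consumed in a fixed,
documented order (expression → interactome → compounds → annotations),
so identical configs give bit-identical bundles and later additions
cannot silently shift earlier outputs; each generator also accepts its
own seed. The generator does **not** model probe-level effects, batch
effects, correlated gene modules, or realistic interactome clustering —
passing tests demonstrate the pipeline's statistical and algorithmic
correctness under its stated assumptions, not performance on real
microarray or curated-interactome data.

## Problem sizes and numerics

The calibration studies use 2000-gene matrices (200 null replicates for
type-I error; 20 replicates for sensitivity), 20 interactome replicates
of 500 nodes for hub recovery, and oracle sweeps over ~1200 atlas
graphs, 200 random graphs up to 30 nodes, all hypergeometric instances
with N ≤ 25 and ~15 000 AUC instances — sizes at which the brute-force
oracles remain exact and the whole suite completes in well under a
minute each. Oracle agreement is asserted at 1e−12; all fixture-table
checks are exact.

## Known limitations

- Welch's t is a stand-in: studies fit with moderated linear models will
  not reproduce gene-for-gene p-values, only the same calling logic.
- The published headline counts of the motivating study (compound,
  target, DEG and network-node counts) depend on 2020-era database
  versions and are not reproducible offline; the package verifies the
  published-table consistencies and the algorithmic properties instead.
- Kappa grouping emulates, but does not replicate, the term clustering
  of interactive enrichment browsers.
- No confidence intervals on AUC (DeLong/bootstrap) yet.
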