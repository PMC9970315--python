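# Methods

## Consensus miRNA targeting

Each prediction tool contributes a set of (miRNA, gene) claims; a pair
is kept when at least `min_tools` (default 3 of the 5 emulated tools)
*distinct* tools predict it, and the per-miRNA union of kept pairs is
the target set. Votes are tool-level: duplicate rows within one tool
count once. Identifiers are matched case-insensitively (lower-cased);
no ortholog or alias mapping is attempted, so rat/human symbol
mismatches must be resolved upstream. Tool-native scores are carried
through unmodified and never combined — the rule is a vote, not a rank
aggregation — and no tool-specific score cutoff is applied before
voting.

## Network model

The integrated network is a typed directed multigraph with three node
types (miRNA, gene, TF) and three edge types:

* `ppi` — protein–protein interactions between gene/TF nodes. PPI is
  undirected; each unique pair is materialized as two directed arcs so
  a single traversal engine serves all layers and PPI edges can bridge
  any segment of a directed source→target chain.
* `tf_mirna` — TF→miRNA transcriptional regulation.
* `mirna_target` — consensus miRNA→gene targeting.

A node has exactly one type: an id declared as a TF is typed TF even
where it also appears in the PPI layer; an id used both as a miRNA and
as a protein is rejected as contradictory. Being a path source or
target is a *role* overlay rather than a type, because a molecule like
TGF-β1 is simultaneously a gene node and the source. Self-loops are
dropped with a warning. Edges carry no weight or sign; whether a
regulation is activating or repressive is a biological interpretation
layered on afterwards, not encoded in the topology.

## Path search

`enumerate_paths` performs depth-first search with three constraints:
simple paths only (no node revisited along a branch, which guarantees
termination on cyclic graphs), a depth bound `max_depth` in edges
(default 4 — enough for chains with up to three mediator layers while
bounding the combinatorial growth), and an optional edge-type filter
(e.g. excluding `ppi` restricts paths to purely regulatory chains; the
default allows PPI edges anywhere). Children are expanded in
lexicographic id order and results are sorted by (depth, node
sequence), so output is reproducible and independent of input row
order. `source == target` returns no paths by convention: the analysis
asks for mediators between distinct molecules. `reachable_nodes` is the
breadth-first depth-truncated transitive closure; `build_search_tree`
materializes the full DFS expansion, whose root-to-target branches
flatten to exactly the enumerated path set (a tested invariant).

## ΔΔCt quantification

Technical replicate Cts within a sample are averaged; per-sample
ΔCt = Ct_gene − Ct_reference; group ΔCt is the mean of per-sample ΔCts
(with balanced data this equals the difference-of-mean-Cts form);
ΔΔCt = ΔCt_treated − ΔCt_control and fold = 2^−ΔΔCt. Samples missing
either Ct are dropped with a warning; a group left empty is an error.
Percent suppression uses the reduced-BY convention, 100·(1 − fold), so
fold 0.42 is 58% suppression; the package also exposes
100·(fold − 1) for inductions and the inverse conversion, because
"suppressed by x%" and "suppressed to x%" are easily conflated in the
literature. Amplification-efficiency (Pfaffl) correction is out of
scope; 100% efficiency is assumed.

## Two-sample comparison

The pooled (equal-variance, Student's independent) t-test is used, not
Welch: df = n₁ + n₂ − 2 and
t = (m₁ − m₂)/√(s²ₚ(1/n₁ + 1/n₂)) with
s²ₚ = ((n₁−1)s₁² + (n₂−1)s₂²)/df. The summary-statistic form
`t_test_from_summary` is exactly equivalent to the raw form on data
with the same summaries (a tested invariant, checked against an
independent reference implementation to 1e−10) and allows published
mean ± SD ± n triplets to be re-analyzed directly. Degenerate inputs:
zero pooled variance with equal means yields t = 0, p = 1; with unequal
means the statistic is undefined and rejected. p-values are rounded to
three decimals in printed summaries. No multiple-testing correction is
applied (the analysis reports three pre-specified biomarkers).

## Synthetic-data generator

The generator defines the study conditions under which the pipeline is
validated.

**Interaction tables.** Planted source→…→target node chains are typed
by inference (`miR*` → miRNA, declared ids → TF, rest gene) and each
edge is routed to the table matching its endpoint types; an impossible
transition (e.g. gene→miRNA without TF status, miRNA→miRNA) is rejected
naming the edge. Decoy structure: Erdős–Rényi PPI edges over all
protein-coding nodes at `ppi_edge_prob`, decoy TF→miRNA edges at
probability 0.2, and per-tool prediction tables in which each true
planted target is emitted by each tool with probability 0.8 (topped up
to the `min_tools` floor so consensus always keeps it) and each decoy
(miRNA, gene) pair with probability 0.1. Decoy edges that would create
a source→target path shorter than the shortest planted path are
deleted, so planted paths remain discoverable at their planted depth.
With zero decoy nodes all random edge generation is disabled and the
output is exactly the planted structure, giving precision = recall = 1
as a hard test point. The emulated databases are miniature: tens of
nodes rather than the thousands of proteins a real PPI database
contributes; topology is the simplest tunable-density null
(Erdős–Rényi), not scale-free, so degree-distribution effects on path
counts are not represented.

**qPCR tables.** Expected Ct is `baseline_ct − log2(fold)` relative to
the control group (reference gene flat at `baseline_ct`, default 24
cycles — mid-dynamic-range, arbitrary and configurable), with i.i.d.
Gaussian noise per (sample, gene) measurement. Defaults are 6
replicates per group and 0.25-cycle noise, typical of careful
technical-replicate qPCR. The model omits efficiency differences
between genes, plate effects and correlated replicate noise; recovery
results show estimator behaviour under ideal noise, not assay-specific
bias. Note that averaging per-experiment folds 2^−ΔΔCt across
simulations carries a small convexity (Jensen) bias — about +1% of the
fold at these settings — visible as mean suppression estimates sitting
a fraction of a percentage point below the planted value.

**Serum cohort.** Two arms of 24 (no calcification) and 11 (severe
calcification) subjects with per-group biomarker normals taken from the
published mean ± SD values, age 75.8 ± 6.0 years and a 13/35 male
split. Concentrations are drawn normal and clipped at zero by default —
a deliberate simplification: a printed mean of 1.85 with SD 3.36
implies strong right-skew that a clipped normal only approximates, so
simulated group SDs run slightly below specification when clipping
bites.

## Pipeline orchestration

One YAML file drives generate → consensus → build → search → stats.
Every produced file is listed in a manifest with its SHA-256 checksum;
identical config + seed reproduce identical checksums (timestamps are
recorded but excluded from comparison). Stage failures abort with the
stage name; no stage mutates a prior stage's outputs.

## Problem sizes

Validation runs use desk-scale problems chosen to exercise every code
path: random digraphs of ≤ 10 nodes against brute-force and
matrix-power oracles (200 graphs), consensus fixtures of ≤ 50 pairs
against exhaustive counting, demo networks of ~20 decoy genes, and
500-simulation Monte-Carlo recovery of planted qPCR effects at
6 replicates/group.

## Known limitations

* No path significance testing or network-randomization null; the path
  enumeration is descriptive, as is the analysis it implements.
* No ortholog mapping; mixed-species symbol sets silently fail to
  match unless pre-harmonized.
* The depth bound and edge-type policy are analysis choices exposed as
  configuration, with defaults (depth 4, all edge types) documented
  above.
* Regulatory sign (activation vs repression) is not modeled.
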