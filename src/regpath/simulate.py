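"""Synthetic inputs for the regulatory-path pipeline.

Every downstream stage (consensus voting, network building, path search,
expression statistics) can be exercised without any database download by
generating miniature versions of its inputs here:

* :func:`gen_interaction_db` — a small PPI edge list, a TF→miRNA
  regulation table and five correlated miRNA-target prediction tables,
  with one or more *planted* source→…→target regulatory paths hidden
  among Erdős–Rényi decoy edges.  The planted paths are returned as a
  truth list so recovery can be scored.
* :func:`gen_qpcr` — a long-format qPCR Ct table in which each gene's
  relative expression versus the control group is planted as a fold
  change, realized as a Ct shift of ``-log2(fold)`` plus Gaussian
  replicate noise.
* :func:`gen_cohort` — a two(+)-group serum cohort with per-group
  biomarker means ± SD, ages and a sex split.

All randomness flows from the ``seed`` in each config; identical config
and seed give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_TOOLS",
    "NetworkSimConfig",
    "QpcrSimConfig",
    "CohortGroupSpec",
    "CohortSimConfig",
    "PlantedPath",
    "InteractionDB",
    "gen_interaction_db",
    "gen_qpcr",
    "gen_cohort",
    "default_cohort_config",
]

#: The five target-prediction tools whose votes are emulated.
DEFAULT_TOOLS = ("DIANA", "Miranda", "PicTar", "TargetScan", "miRDB")

NODE_TYPES = ("miRNA", "gene", "TF")
EDGE_TYPES = ("ppi", "tf_mirna", "mirna_target")


def infer_node_type(node_id: str, tf_ids=(), overrides=None) -> str:
    """miRNA if the id looks like one (``miR*``/``*-miR-*``), TF if declared
    or named ``TF*``, gene otherwise. ``overrides`` wins when given."""
    if overrides and node_id in overrides:
        return overrides[node_id]
    if node_id in tf_ids:
        return "TF"
    low = node_id.lower()
    if low.startswith("mir") or "-mir-" in low:
        return "miRNA"
    if node_id.upper().startswith("TF"):
        return "TF"
    return "gene"


def classify_edge(type_from: str, type_to: str) -> str:
    """Edge type implied by the endpoint node types.

    TF→miRNA is transcriptional regulation, miRNA→gene is targeting, and
    any pair of protein-coding nodes (gene/TF) is a PPI contact.  All
    other transitions (miRNA→miRNA, gene→miRNA, miRNA→TF) have no edge
    table to live in and raise ``ValueError``.
    """
    if type_to == "miRNA":
        if type_from == "TF":
            return "tf_mirna"
        raise ValueError(
            f"invalid transition {type_from}→miRNA (only TF→miRNA is allowed)"
        )
    if type_from == "miRNA":
        if type_to == "gene":
            return "mirna_target"
        raise ValueError(
            f"invalid transition miRNA→{type_to} (miRNAs target genes)"
        )
    return "ppi"


@dataclass(frozen=True)
class PlantedPath:
    """A ground-truth source→target path with its per-edge types."""

    nodes: tuple
    edge_types: tuple

    @property
    def source(self) -> str:
        return self.nodes[0]

    @property
    def target(self) -> str:
        return self.nodes[-1]

    @property
    def depth(self) -> int:
        return len(self.nodes) - 1


@dataclass
class NetworkSimConfig:
    """Configuration for :func:`gen_interaction_db`.

    Parameters
    ----------
    planted_paths
        Node-id sequences; each must start at the same source and end at
        the same target.  Node types are inferred from ids (``miR*`` →
        miRNA, ``TF*`` or ``node_types`` override → TF, else gene).
    n_decoy_genes, n_tfs, n_mirnas
        Decoy nodes added on top of the planted ones.
    ppi_edge_prob
        Erdős–Rényi edge probability among protein-coding (gene/TF)
        nodes.
    tf_mirna_edge_prob
        Probability of each decoy TF→miRNA regulation edge.
    p_tool, p_decoy
        Per-tool emission probability of a true planted target and of a
        decoy (miRNA, gene) pair in the prediction tables.
    min_tools
        Vote floor guaranteed (by top-up resampling) for every planted
        miRNA→gene edge, so the consensus stage always keeps it.
    """

    planted_paths: list
    n_decoy_genes: int = 0
    n_tfs: int = 0
    n_mirnas: int = 0
    ppi_edge_prob: float = 0.1
    tf_mirna_edge_prob: float = 0.2
    p_tool: float = 0.8
    p_decoy: float = 0.1
    min_tools: int = 3
    tools: tuple = DEFAULT_TOOLS
    node_types: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if not self.planted_paths:
            raise ValueError("at least one planted path is required")
        for p in (self.ppi_edge_prob, self.tf_mirna_edge_prob, self.p_tool,
                  self.p_decoy):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for n in (self.n_decoy_genes, self.n_tfs, self.n_mirnas):
            if n < 0:
                raise ValueError("counts must be nonnegative")
        if not 1 <= self.min_tools <= len(self.tools):
            raise ValueError("min_tools must be in [1, number of tools]")
        src = {p[0] for p in self.planted_paths}
        tgt = {p[-1] for p in self.planted_paths}
        if len(src) != 1 or len(tgt) != 1:
            raise ValueError(
                "all planted paths must share one source and one target"
            )
        for path in self.planted_paths:
            if len(path) < 2:
                raise ValueError(f"planted path {path} has length < 1 edge")
            if len(set(path)) != len(path):
                raise ValueError(f"planted path {path} repeats a node")

    @property
    def source(self) -> str:
        return self.planted_paths[0][0]

    @property
    def target(self) -> str:
        return self.planted_paths[0][-1]


@dataclass(frozen=True)
class InteractionDB:
    """Output bundle of :func:`gen_interaction_db`."""

    ppi_edges: pd.DataFrame          # protein_a, protein_b
    tf_mirna_edges: pd.DataFrame     # tf, mirna
    prediction_tables: dict          # tool -> DataFrame(mirna, gene, score)
    truth: list                      # list[PlantedPath]
    tf_ids: frozenset
    source: str
    target: str


def _planted_edges(config: NetworkSimConfig, types: dict) -> list:
    """Typed (u, v, edge_type) for every planted-path edge; validates
    node-type transitions."""
    edges = []
    for path in config.planted_paths:
        for u, v in zip(path, path[1:]):
            try:
                et = classify_edge(types[u], types[v])
            except ValueError as exc:
                raise ValueError(f"planted edge {u}→{v}: {exc}") from exc
            edges.append((u, v, et))
    return edges


def gen_interaction_db(config: NetworkSimConfig) -> InteractionDB:
    """Generate PPI, TF→miRNA and per-tool prediction tables with planted
    ground-truth paths.

    Guarantees, deterministic under ``config.seed``:

    * every planted edge appears in the table matching its type, and every
      planted miRNA→gene edge is emitted by at least ``min_tools`` tools;
    * no decoy edge creates a source→target path shorter than the
      shortest planted one (offending decoys are deleted).
    """
    rng = np.random.default_rng(config.seed)

    planted_nodes = sorted({n for p in config.planted_paths for n in p})
    types = {
        n: infer_node_type(n, overrides=config.node_types)
        for n in planted_nodes
    }
    planted = _planted_edges(config, types)
    truth = [
        PlantedPath(
            nodes=tuple(path),
            edge_types=tuple(
                classify_edge(types[u], types[v])
                for u, v in zip(path, path[1:])
            ),
        )
        for path in config.planted_paths
    ]

    decoy_genes = [f"G{i:03d}" for i in range(1, config.n_decoy_genes + 1)]
    decoy_tfs = [f"TF{i:02d}" for i in range(1, config.n_tfs + 1)]
    decoy_mirnas = [f"miR-d{i:02d}" for i in range(1, config.n_mirnas + 1)]
    for n in decoy_genes:
        types[n] = "gene"
    for n in decoy_tfs:
        types[n] = "TF"
    for n in decoy_mirnas:
        types[n] = "miRNA"

    proteins = sorted(n for n, t in types.items() if t in ("gene", "TF"))
    mirnas = sorted(n for n, t in types.items() if t == "miRNA")
    tfs = sorted(n for n, t in types.items() if t == "TF")
    genes = sorted(n for n, t in types.items() if t == "gene")

    # with zero decoy nodes the output is exactly the planted structure
    any_decoys = bool(
        config.n_decoy_genes or config.n_tfs or config.n_mirnas
    )

    ppi_pairs = {
        tuple(sorted((u, v))) for u, v, et in planted if et == "ppi"
    }
    n_planted_ppi = len(ppi_pairs)
    if any_decoys:
        for i, a in enumerate(proteins):
            for b in proteins[i + 1:]:
                if (a, b) not in ppi_pairs and \
                        rng.random() < config.ppi_edge_prob:
                    ppi_pairs.add((a, b))

    tfm_edges = {(u, v) for u, v, et in planted if et == "tf_mirna"}
    n_planted_tfm = len(tfm_edges)
    if any_decoys:
        for tf in tfs:
            for mi in mirnas:
                if (tf, mi) not in tfm_edges and \
                        rng.random() < config.tf_mirna_edge_prob:
                    tfm_edges.add((tf, mi))

    # prediction tables: tool -> set of (mirna, gene)
    true_targets = sorted(
        {(u, v) for u, v, et in planted if et == "mirna_target"}
    )
    tool_sets = {tool: set() for tool in config.tools}
    for pair in true_targets:
        emitting = [t for t in config.tools if rng.random() < config.p_tool]
        if len(emitting) < config.min_tools:
            # top up with uniformly chosen extra tools so consensus keeps it
            missing = [t for t in config.tools if t not in emitting]
            extra = rng.choice(
                len(missing),
                size=config.min_tools - len(emitting),
                replace=False,
            )
            emitting += [missing[i] for i in sorted(extra)]
        for tool in emitting:
            tool_sets[tool].add(pair)
    if any_decoys:
        decoy_pairs = [
            (mi, g)
            for mi in mirnas
            for g in genes
            if (mi, g) not in set(true_targets)
        ]
        for pair in decoy_pairs:
            for tool in config.tools:
                if rng.random() < config.p_decoy:
                    tool_sets[tool].add(pair)

    # prune decoys that shortcut the source→target distance
    _prune_shortcuts(config, planted, ppi_pairs, tfm_edges, tool_sets)

    if config.n_decoy_genes or config.n_tfs or config.n_mirnas:
        assert len(ppi_pairs) >= n_planted_ppi
        assert len(tfm_edges) >= n_planted_tfm

    ppi_df = pd.DataFrame(
        sorted(ppi_pairs), columns=["protein_a", "protein_b"]
    )
    tfm_df = pd.DataFrame(sorted(tfm_edges), columns=["tf", "mirna"])
    pred_tables = {}
    for tool in config.tools:
        rows = sorted(tool_sets[tool])
        scores = rng.uniform(0.5, 1.0, size=len(rows)).round(4)
        pred_tables[tool] = pd.DataFrame(
            [(mi, g, s) for (mi, g), s in zip(rows, scores)],
            columns=["mirna", "gene", "score"],
        )
    return InteractionDB(
        ppi_edges=ppi_df,
        tf_mirna_edges=tfm_df,
        prediction_tables=pred_tables,
        truth=truth,
        tf_ids=frozenset(tfs),
        source=config.source,
        target=config.target,
    )


def _effective_graph(ppi_pairs, tfm_edges, tool_sets, min_tools):
    """Directed graph as the downstream pipeline would see it (prediction
    edges only where >= min_tools tools vote)."""
    g = nx.DiGraph()
    for a, b in ppi_pairs:
        g.add_edge(a, b)
        g.add_edge(b, a)
    g.add_edges_from(tfm_edges)
    votes = {}
    for pairs in tool_sets.values():
        for pair in pairs:
            votes[pair] = votes.get(pair, 0) + 1
    for (mi, gene), v in votes.items():
        if v >= min_tools:
            g.add_edge(mi, gene)
    return g


def _prune_shortcuts(config, planted, ppi_pairs, tfm_edges, tool_sets):
    """Delete decoy edges until no source→target path is shorter than the
    shortest planted path. Mutates the edge containers in place."""
    min_len = min(len(p) - 1 for p in config.planted_paths)
    planted_dir = {(u, v) for u, v, _ in planted}
    planted_undir = planted_dir | {(v, u) for u, v, _ in planted}
    while True:
        g = _effective_graph(ppi_pairs, tfm_edges, tool_sets,
                             config.min_tools)
        if config.source not in g or config.target not in g:
            return
        try:
            short = nx.shortest_path(g, config.source, config.target)
        except nx.NetworkXNoPath:
            return
        if len(short) - 1 >= min_len:
            return
        removed = False
        for u, v in zip(short, short[1:]):
            if (u, v) in planted_undir:
                continue
            key = tuple(sorted((u, v)))
            if key in ppi_pairs:
                ppi_pairs.discard(key)
            elif (u, v) in tfm_edges:
                tfm_edges.discard((u, v))
            else:
                for pairs in tool_sets.values():
                    pairs.discard((u, v))
            removed = True
            break
        if not removed:  # pragma: no cover - planted paths define min_len
            return


@dataclass
class QpcrSimConfig:
    """Configuration for :func:`gen_qpcr`.

    ``fold_changes[group][gene]`` is the planted relative expression of
    ``gene`` in ``group`` versus ``control_group`` (genes or groups left
    out default to fold 1).  Each measurement's expected Ct is
    ``baseline_ct - log2(fold)``; the reference gene always sits at
    ``baseline_ct``.  Gaussian noise of SD ``ct_noise_sd`` cycles is
    added independently per (sample, gene) measurement.
    """

    genes: list
    fold_changes: dict
    reference_gene: str = "GAPDH"
    control_group: str = "control"
    n_replicates: int = 6
    ct_noise_sd: float = 0.25
    baseline_ct: float = 24.0
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if self.reference_gene not in self.genes:
            raise ValueError(
                f"reference gene '{self.reference_gene}' not in gene list"
            )
        for group, folds in self.fold_changes.items():
            for gene, fold in folds.items():
                if gene not in self.genes:
                    raise ValueError(f"fold planted for unknown gene '{gene}'")
                if not fold > 0:
                    raise ValueError(
                        f"planted fold for {gene} in {group} must be > 0"
                    )

    @property
    def groups(self) -> list:
        extra = [g for g in self.fold_changes if g != self.control_group]
        return [self.control_group] + sorted(extra)


def gen_qpcr(config: QpcrSimConfig) -> pd.DataFrame:
    """Simulate a long-format qPCR table ``sample, group, gene, ct``."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for group in config.groups:
        folds = config.fold_changes.get(group, {})
        for i in range(config.n_replicates):
            sample = f"{group}_{i + 1}"
            for gene in config.genes:
                if gene == config.reference_gene or group == \
                        config.control_group:
                    fold = 1.0
                else:
                    fold = folds.get(gene, 1.0)
                ct = config.baseline_ct - np.log2(fold)
                if config.ct_noise_sd > 0:
                    ct += rng.normal(0.0, config.ct_noise_sd)
                rows.append((sample, group, gene, float(ct)))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])


@dataclass
class CohortGroupSpec:
    """One cohort arm: size, biomarker normals, age normal, sex split."""

    label: str
    n: int
    biomarkers: dict          # name -> (mean, sd)
    age_mean: float = 75.8
    age_sd: float = 6.0
    sex_ratio: float = 0.37   # fraction assigned to the counted sex category

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"group '{self.label}' needs n >= 2")
        for name, spec in self.biomarkers.items():
            try:
                mean, sd = spec
            except (TypeError, ValueError):
                raise ValueError(
                    f"biomarker '{name}' in group '{self.label}' must give "
                    f"(mean, sd); missing SD?"
                ) from None
            if sd < 0:
                raise ValueError(f"SD for '{name}' must be >= 0")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")


@dataclass
class CohortSimConfig:
    group_specs: list
    nonnegative_clip: bool = True
    sex_category: str = "M"
    other_sex: str = "F"
    seed: int = 0

    def __post_init__(self):
        if not self.group_specs:
            raise ValueError("at least one group is required")
        names = [frozenset(g.biomarkers) for g in self.group_specs]
        if len(set(names)) != 1:
            raise ValueError(
                "all groups must declare the same biomarkers (a biomarker "
                "is missing its mean/SD in some group)"
            )


def gen_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Simulate a serum cohort ``subject, group, sex, age, <biomarkers>``.

    Biomarker and age values are drawn from per-group normals; with
    ``nonnegative_clip`` biomarker draws are clipped at 0 (a deliberate
    simplification for concentrations whose printed SD exceeds the mean).
    The counted sex category gets exactly ``round(n * sex_ratio)``
    subjects per group.
    """
    rng = np.random.default_rng(config.seed)
    biomarker_names = sorted(config.group_specs[0].biomarkers)
    rows = []
    subject = 0
    for spec in config.group_specs:
        n_cat = int(round(spec.n * spec.sex_ratio))
        for i in range(spec.n):
            subject += 1
            sex = config.sex_category if i < n_cat else config.other_sex
            age = float(rng.normal(spec.age_mean, spec.age_sd))
            values = []
            for name in biomarker_names:
                mean, sd = spec.biomarkers[name]
                v = float(rng.normal(mean, sd))
                if config.nonnegative_clip:
                    v = max(v, 0.0)
                values.append(v)
            rows.append(
                [f"S{subject:04d}", spec.label, sex, age] + values
            )
    return pd.DataFrame(
        rows, columns=["subject", "group", "sex", "age"] + biomarker_names
    )


def default_cohort_config(seed: int = 0) -> CohortSimConfig:
    """Two-arm older-adult cohort: 24 without aortic arch calcification
    and 11 with severe AAC, with serum TGF-β1 / CTGF (ng/mL) and relative
    circulating miR-378a-3p levels."""
    return CohortSimConfig(
        group_specs=[
            CohortGroupSpec(
                label="non-AAC",
                n=24,
                biomarkers={
                    "TGFB1": (9.62, 8.25),
                    "CTGF": (24.93, 6.39),
                    "miR-378a-3p": (0.55, 0.763),
                },
                sex_ratio=9 / 24,
            ),
            CohortGroupSpec(
                label="severe-AAC",
                n=11,
                biomarkers={
                    "TGFB1": (1.85, 3.36),
                    "CTGF": (19.98, 7.11),
                    "miR-378a-3p": (0.134, 0.207),
                },
                sex_ratio=4 / 11,
            ),
        ],
        seed=seed,
    )
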