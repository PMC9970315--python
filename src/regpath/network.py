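"""Typed heterogeneous regulatory network construction.

Merges three interaction layers into one directed multigraph over
miRNA / gene / TF nodes:

* protein–protein interactions (undirected; materialized as two directed
  arcs so a single traversal engine serves every layer),
* TF→miRNA transcriptional regulation,
* consensus miRNA→gene targeting from :mod:`regpath.consensus`.

Node types are inferred (ids seen as miRNAs become miRNA, declared TFs
become TF, the rest gene) and must be consistent across layers; an id
used both as a miRNA and as a PPI protein is rejected by name.  A gene
that is also a declared TF takes the single type TF; being a path source
or target is a *role* overlay, not a type, because a molecule such as
TGF-β1 is simultaneously a gene and the source.  Identifiers are matched
case-insensitively (lower-cased), consistent with the consensus stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NODE_TYPES",
    "EDGE_TYPES",
    "RegNode",
    "RegEdge",
    "RegNetwork",
    "build_network",
    "validate_network",
    "write_network",
    "read_network",
    "write_graphml",
    "write_sif",
]

NODE_TYPES = ("miRNA", "gene", "TF")
EDGE_TYPES = ("ppi", "tf_mirna", "mirna_target")


def normalize_id(identifier) -> str:
    return str(identifier).strip().lower()


@dataclass(frozen=True)
class RegNode:
    id: str
    node_type: str
    role: str = "none"  # source | target | none

    def __post_init__(self):
        if self.node_type not in NODE_TYPES:
            raise ValueError(f"unknown node type '{self.node_type}'")
        if self.role not in ("source", "target", "none"):
            raise ValueError(f"unknown role '{self.role}'")


@dataclass(frozen=True)
class RegEdge:
    src: str
    dst: str
    edge_type: str
    provenance: str = ""

    def __post_init__(self):
        if self.edge_type not in EDGE_TYPES:
            raise ValueError(f"unknown edge type '{self.edge_type}'")
        if self.src == self.dst:
            raise ValueError(f"self-loop {self.src}→{self.dst}")


@dataclass
class RegNetwork:
    """Directed multigraph with typed nodes/edges and source/target roles.

    Thin wrapper over a :class:`networkx.MultiDiGraph` (node attribute
    ``node_type``; edge key and attribute ``edge_type``, attribute
    ``provenance``) plus the declared source and target id lists.
    """

    graph: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)
    source_ids: list = field(default_factory=list)
    target_ids: list = field(default_factory=list)

    # -- queries ---------------------------------------------------------
    def __contains__(self, node_id) -> bool:
        return node_id in self.graph

    @property
    def nodes(self) -> list:
        return [
            RegNode(n, d["node_type"], d.get("role", "none"))
            for n, d in sorted(self.graph.nodes(data=True))
        ]

    @property
    def edges(self) -> list:
        return sorted(
            (
                RegEdge(u, v, d["edge_type"], d.get("provenance", ""))
                for u, v, d in self.graph.edges(data=True)
            ),
            key=lambda e: (e.src, e.dst, e.edge_type),
        )

    def node_type(self, node_id) -> str:
        return self.graph.nodes[node_id]["node_type"]

    def successors(self, node_id, edge_types=None):
        """Sorted ``(neighbor, edge_type)`` pairs leaving ``node_id``."""
        out = {
            (v, d["edge_type"])
            for _, v, d in self.graph.out_edges(node_id, data=True)
            if edge_types is None or d["edge_type"] in edge_types
        }
        return sorted(out)

    def n_edges_by_type(self) -> dict:
        counts = dict.fromkeys(EDGE_TYPES, 0)
        for _, _, d in self.graph.edges(data=True):
            counts[d["edge_type"]] += 1
        return counts


def _set_type(types: dict, node_id: str, node_type: str, where: str):
    prev = types.get(node_id)
    if prev is not None and prev != node_type:
        raise ValueError(
            f"id '{node_id}' used with contradictory types: {prev} vs "
            f"{node_type} (in {where})"
        )
    types[node_id] = node_type


def build_network(
    ppi: pd.DataFrame,
    tf_mirna: pd.DataFrame,
    consensus,
    sources,
    targets,
    tf_ids=(),
) -> RegNetwork:
    """Merge the three layers into one :class:`RegNetwork`.

    Parameters
    ----------
    ppi
        Two-column undirected edge list (``protein_a, protein_b``); each
        unique pair yields two directed ``ppi`` arcs.
    tf_mirna
        ``tf, mirna`` regulation table; rows become ``tf_mirna`` arcs.
    consensus
        Iterable of :class:`~regpath.consensus.ConsensusTargetSet` (or an
        equivalent ``mirna, gene`` frame) providing ``mirna_target`` arcs.
    sources, targets
        Ids flagged with the source / target role; must exist as nodes.
    tf_ids
        Ids to type as TF (beyond those in the ``tf`` column).
    """
    if not list(sources) or not list(targets):
        raise ValueError("sources and targets must be non-empty")

    ppi_pairs = set()
    if ppi is not None and len(ppi):
        a_col, b_col = ppi.columns[:2]
        for row in ppi.itertuples(index=False):
            u = normalize_id(getattr(row, a_col))
            v = normalize_id(getattr(row, b_col))
            if u == v:
                warnings.warn(f"dropping PPI self-loop {u}", stacklevel=2)
                continue
            ppi_pairs.add(tuple(sorted((u, v))))

    tfm_pairs = set()
    if tf_mirna is not None and len(tf_mirna):
        for row in tf_mirna.itertuples(index=False):
            u, v = normalize_id(row.tf), normalize_id(row.mirna)
            if u == v:
                warnings.warn(f"dropping TF→miRNA self-loop {u}",
                              stacklevel=2)
                continue
            tfm_pairs.add((u, v))

    target_pairs = set()
    if consensus is not None:
        if isinstance(consensus, pd.DataFrame):
            items = [
                (normalize_id(r.mirna), normalize_id(r.gene))
                for r in consensus.itertuples(index=False)
            ]
        else:
            items = [
                (normalize_id(c.mirna), normalize_id(g))
                for c in consensus
                for g in sorted(c.targets)
            ]
        for u, v in items:
            if u == v:
                warnings.warn(f"dropping miRNA-target self-loop {u}",
                              stacklevel=2)
                continue
            target_pairs.add((u, v))

    tf_set = {normalize_id(t) for t in tf_ids} | {u for u, _ in tfm_pairs}

    types: dict = {}
    for u, v in sorted(tfm_pairs):
        _set_type(types, u, "TF", "TF→miRNA table")
        _set_type(types, v, "miRNA", "TF→miRNA table")
    for u, v in sorted(target_pairs):
        _set_type(types, u, "miRNA", "consensus targets")
        _set_type(types, v, "TF" if v in tf_set else "gene",
                  "consensus targets")
    for u, v in sorted(ppi_pairs):
        for n in (u, v):
            _set_type(types, n, "TF" if n in tf_set else "gene", "PPI table")
    for t in sorted(tf_set):
        _set_type(types, t, "TF", "declared TF ids")

    src_ids = [normalize_id(s) for s in sources]
    tgt_ids = [normalize_id(t) for t in targets]
    for n in src_ids + tgt_ids:
        if n not in types:
            raise ValueError(
                f"declared source/target '{n}' does not appear in any "
                f"interaction table"
            )

    g = nx.MultiDiGraph()
    for n, t in sorted(types.items()):
        role = "source" if n in src_ids else (
            "target" if n in tgt_ids else "none"
        )
        g.add_node(n, node_type=t, role=role)
    for u, v in sorted(ppi_pairs):
        g.add_edge(u, v, key="ppi", edge_type="ppi", provenance="ppi_table")
        g.add_edge(v, u, key="ppi", edge_type="ppi", provenance="ppi_table")
    for u, v in sorted(tfm_pairs):
        g.add_edge(u, v, key="tf_mirna", edge_type="tf_mirna",
                   provenance="tf_mirna_table")
    for u, v in sorted(target_pairs):
        g.add_edge(u, v, key="mirna_target", edge_type="mirna_target",
                   provenance="consensus")

    net = RegNetwork(graph=g, source_ids=src_ids, target_ids=tgt_ids)
    counts = net.n_edges_by_type()
    logger.info(
        "built network: %d nodes, %d edges (%s)",
        g.number_of_nodes(),
        g.number_of_edges(),
        ", ".join(f"{k}={v}" for k, v in counts.items()),
    )
    return net


def validate_network(net: RegNetwork) -> list:
    """Report invariant violations without mutating the network.

    Checks dangling edge endpoints, self-loops, illegal edge/endpoint
    type combinations, and missing source/target nodes.  Returns a list
    of human-readable violation strings (empty on a valid network).
    """
    g = net.graph
    violations = []
    for u, v, d in g.edges(data=True):
        et = d.get("edge_type")
        for n in (u, v):
            if n not in g.nodes or "node_type" not in g.nodes[n]:
                violations.append(f"dangling endpoint '{n}' on edge {u}→{v}")
        if u == v:
            violations.append(f"self-loop on '{u}' ({et})")
            continue
        tu = g.nodes.get(u, {}).get("node_type")
        tv = g.nodes.get(v, {}).get("node_type")
        if et == "tf_mirna" and (tu, tv) != ("TF", "miRNA"):
            violations.append(
                f"tf_mirna edge {u}→{v} joins {tu}→{tv}, expected TF→miRNA"
            )
        elif et == "mirna_target" and not (
            tu == "miRNA" and tv in ("gene", "TF")
        ):
            violations.append(
                f"mirna_target edge {u}→{v} joins {tu}→{tv}, expected "
                f"miRNA→gene"
            )
        elif et == "ppi" and not (
            tu in ("gene", "TF") and tv in ("gene", "TF")
        ):
            violations.append(
                f"ppi edge {u}→{v} joins {tu}→{tv}, expected gene/TF pair"
            )
        elif et not in EDGE_TYPES:
            violations.append(f"unknown edge type '{et}' on {u}→{v}")
    for n in net.source_ids + net.target_ids:
        if n not in g:
            violations.append(f"declared source/target '{n}' missing")
    return violations


# -- serialization -------------------------------------------------------

def write_network(net: RegNetwork, nodes_path, edges_path):
    """Write the node and edge TSV pair."""
    nodes = pd.DataFrame(
        [(n.id, n.node_type, n.role) for n in net.nodes],
        columns=["id", "node_type", "role"],
    )
    edges = pd.DataFrame(
        [(e.src, e.dst, e.edge_type, e.provenance) for e in net.edges],
        columns=["src", "dst", "edge_type", "provenance"],
    )
    nodes.to_csv(nodes_path, sep="\t", index=False)
    edges.to_csv(edges_path, sep="\t", index=False)


def read_network(nodes_path, edges_path) -> RegNetwork:
    """Rebuild a :class:`RegNetwork` from its node/edge TSV pair."""
    nodes = pd.read_csv(nodes_path, sep="\t")
    edges = pd.read_csv(edges_path, sep="\t", keep_default_na=False)
    g = nx.MultiDiGraph()
    for row in nodes.itertuples(index=False):
        g.add_node(row.id, node_type=row.node_type, role=row.role)
    for row in edges.itertuples(index=False):
        g.add_edge(
            row.src, row.dst, key=row.edge_type,
            edge_type=row.edge_type, provenance=row.provenance,
        )
    return RegNetwork(
        graph=g,
        source_ids=[n.id for n in nodes.itertuples(index=False)
                    if n.role == "source"],
        target_ids=[n.id for n in nodes.itertuples(index=False)
                    if n.role == "target"],
    )


def write_graphml(net: RegNetwork, path):
    nx.write_graphml(net.graph, path)


def write_sif(net: RegNetwork, path):
    """Simple interaction format: ``src<TAB>edge_type<TAB>dst`` per edge."""
    with open(path, "w") as fh:
        for e in net.edges:
            fh.write(f"{e.src}\t{e.edge_type}\t{e.dst}\n")
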