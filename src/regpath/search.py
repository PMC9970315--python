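"""Depth-first exploration of the regulatory network.

Three views of the same bounded search from a source node:

* :func:`reachable_nodes` — every node within ``max_depth`` edges;
* :func:`enumerate_paths` — every *simple* directed source→target path
  of at most ``max_depth`` edges, each exactly once;
* :func:`build_search_tree` — the hierarchical DFS expansion tree whose
  root-to-target branches are exactly those paths.

Simple-path pruning (no node revisited along one branch) guarantees
termination on cyclic graphs; children are expanded in lexicographic id
order so outputs are reproducible regardless of input edge order.  The
default depth bound of 4 edges covers chains with up to three mediator
layers between a source and a target molecule while bounding the
combinatorial growth of the enumeration.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field

import pandas as pd

from .network import EDGE_TYPES, RegNetwork

__all__ = [
    "SearchConfig",
    "PathResult",
    "SearchTree",
    "TreeNode",
    "reachable_nodes",
    "enumerate_paths",
    "build_search_tree",
    "paths_to_table",
    "table_to_paths",
]

NODE_SEP = ";"


@dataclass(frozen=True)
class SearchConfig:
    """Depth bound, optional edge-type filter, child ordering."""

    max_depth: int = 4
    edge_type_filter: frozenset | None = None
    node_ordering: object = None  # key function for child ordering

    def __post_init__(self):
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.edge_type_filter is not None:
            bad = set(self.edge_type_filter) - set(EDGE_TYPES)
            if bad:
                raise ValueError(f"unknown edge types in filter: {bad}")
            object.__setattr__(
                self, "edge_type_filter", frozenset(self.edge_type_filter)
            )

    def sort_key(self):
        return self.node_ordering if self.node_ordering is not None else \
            (lambda pair: pair)


@dataclass(frozen=True)
class PathResult:
    """A simple directed path with the type of each traversed edge."""

    nodes: tuple
    edge_types: tuple

    def __post_init__(self):
        if len(self.edge_types) != len(self.nodes) - 1:
            raise ValueError("edge_types must have one entry per edge")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError(f"path {self.nodes} is not simple")

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
class TreeNode:
    """One DFS expansion: a node reached via ``edge_type`` at ``depth``."""

    id: str
    depth: int
    edge_type: str | None = None  # edge used from the parent; None at root
    children: list = field(default_factory=list)


@dataclass
class SearchTree:
    """Hierarchical DFS search space rooted at a source node."""

    root: TreeNode
    max_depth: int

    def branches_to(self, targets) -> list:
        """Flatten every root-to-target branch into a PathResult, in the
        same (depth, lexicographic) order as :func:`enumerate_paths`."""
        targets = set(targets)
        found = []

        def walk(node, nodes, etypes):
            nodes = nodes + [node.id]
            if node.edge_type is not None:
                etypes = etypes + [node.edge_type]
            if node.id in targets and node.edge_type is not None:
                found.append(
                    PathResult(nodes=tuple(nodes), edge_types=tuple(etypes))
                )
            for child in node.children:
                walk(child, nodes, etypes)

        walk(self.root, [], [])
        return sorted(found, key=lambda p: (p.depth, p.nodes))

    def n_nodes(self) -> int:
        count = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            count += 1
            stack.extend(node.children)
        return count

    def to_text(self) -> str:
        lines = []

        def walk(node, indent):
            label = node.id if node.edge_type is None else \
                f"{node.id} [{node.edge_type}]"
            lines.append("  " * indent + label)
            for child in node.children:
                walk(child, indent + 1)

        walk(self.root, 0)
        return "\n".join(lines)

    def to_json(self, path=None):
        def encode(node):
            return {
                "id": node.id,
                "depth": node.depth,
                "edge_type": node.edge_type,
                "children": [encode(c) for c in node.children],
            }

        payload = {"max_depth": self.max_depth, "root": encode(self.root)}
        if path is not None:
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=2)
        return payload


def _check_node(net: RegNetwork, node_id: str, what: str):
    if node_id not in net:
        raise KeyError(f"{what} node '{node_id}' not in network")


def reachable_nodes(
    net: RegNetwork, source: str, config: SearchConfig = SearchConfig()
) -> set:
    """Nodes reachable from ``source`` within ``max_depth`` edges
    (source included). Traversal-order independent by construction:
    breadth-first levels realize the depth-truncated transitive closure."""
    _check_node(net, source, "source")
    seen = {source}
    frontier = deque([(source, 0)])
    while frontier:
        node, depth = frontier.popleft()
        if depth == config.max_depth:
            continue
        for nbr, _ in net.successors(node, config.edge_type_filter):
            if nbr not in seen:
                seen.add(nbr)
                frontier.append((nbr, depth + 1))
    return seen


def enumerate_paths(
    net: RegNetwork,
    source: str,
    target: str,
    config: SearchConfig = SearchConfig(),
) -> list:
    """All simple directed paths ``source``→``target`` of ≤ ``max_depth``
    edges, each exactly once, sorted by (depth, node sequence).

    ``source == target`` returns ``[]`` by convention: the analysis asks
    for mediators between distinct molecules, not trivial paths.
    """
    _check_node(net, source, "source")
    _check_node(net, target, "target")
    if source == target:
        return []
    key = config.sort_key()
    results = []
    on_branch = {source}
    nodes = [source]
    etypes: list = []

    def dfs(current, depth):
        for nbr, et in sorted(
            net.successors(current, config.edge_type_filter), key=key
        ):
            if nbr in on_branch:
                continue  # simple-path pruning; also guarantees termination
            nodes.append(nbr)
            etypes.append(et)
            if nbr == target:
                results.append(
                    PathResult(nodes=tuple(nodes), edge_types=tuple(etypes))
                )
            elif depth + 1 < config.max_depth:
                on_branch.add(nbr)
                dfs(nbr, depth + 1)
                on_branch.discard(nbr)
            nodes.pop()
            etypes.pop()

    dfs(source, 0)
    return sorted(results, key=lambda p: (p.depth, p.nodes))


def build_search_tree(
    net: RegNetwork, source: str, config: SearchConfig = SearchConfig()
) -> SearchTree:
    """Full DFS expansion tree from ``source`` under the depth bound.

    A node may appear in many branches but never twice on one branch;
    flattening all root-to-target branches reproduces
    :func:`enumerate_paths` exactly.
    """
    _check_node(net, source, "source")
    key = config.sort_key()

    def expand(node_id, depth, on_branch, edge_type):
        node = TreeNode(id=node_id, depth=depth, edge_type=edge_type)
        if depth < config.max_depth:
            for nbr, et in sorted(
                net.successors(node_id, config.edge_type_filter), key=key
            ):
                if nbr in on_branch:
                    continue
                node.children.append(
                    expand(nbr, depth + 1, on_branch | {nbr}, et)
                )
        return node

    root = expand(source, 0, frozenset({source}), None)
    return SearchTree(root=root, max_depth=config.max_depth)


def paths_to_table(paths) -> pd.DataFrame:
    """One row per path: source, target, depth, node chain, edge-type
    chain (``;``-joined). Round-trips losslessly via
    :func:`table_to_paths`."""
    rows = [
        (
            p.source,
            p.target,
            p.depth,
            NODE_SEP.join(p.nodes),
            NODE_SEP.join(p.edge_types),
        )
        for p in paths
    ]
    return pd.DataFrame(
        rows, columns=["source", "target", "depth", "nodes", "edge_types"]
    )


def table_to_paths(table: pd.DataFrame) -> list:
    """Inverse of :func:`paths_to_table`."""
    return [
        PathResult(
            nodes=tuple(row.nodes.split(NODE_SEP)),
            edge_types=tuple(
                row.edge_types.split(NODE_SEP) if row.edge_types else []
            ),
        )
        for row in table.itertuples(index=False)
    ]
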