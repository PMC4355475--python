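"""Enumeration and filtering of source-to-sink regulatory paths.

Candidate regulatory cascades are the simple directed paths that start at a
0-indegree node (an upstream regulator nothing else regulates) and end at a
0-outdegree node (a downstream target that regulates nothing else).  Although
the subnetwork itself may contain cycles (miRNA/TF feedback is common),
each path is acyclic by construction: no node is visited twice.

A candidate becomes a *potential active pathway* when it has at least three
nodes, contains at least one differentially expressed (DE) node, and no two
consecutive "inactive" nodes (non-DE, or lacking expression measurements)
sit between DE nodes.  Path length counts nodes, not edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import AnnotationMissingError
from .network import RegulatoryNetwork
from .subnetwork import NodeAnnotation


@dataclass(frozen=True)
class RegulatoryPath:
    """A simple directed path, stored as its ordered node-id sequence."""

    nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("path visits a node twice (not a simple path)")

    def __len__(self) -> int:
        """Path length, counted in nodes."""
        return len(self.nodes)

    def __str__(self) -> str:
        return " -> ".join(self.nodes)

    @classmethod
    def from_nodes(cls, nodes: Iterable[str]) -> "RegulatoryPath":
        return cls(tuple(nodes))


@dataclass
class PathSearchResult:
    """All paths found by :func:`enumerate_paths`, plus a truncation flag."""

    paths: list[RegulatoryPath] = field(default_factory=list)
    truncated: bool = False

    def __iter__(self) -> Iterator[RegulatoryPath]:
        return iter(self.paths)

    def __len__(self) -> int:
        return len(self.paths)


def find_terminals(net: RegulatoryNetwork) -> tuple[set[str], set[str]]:
    """0-indegree sources and 0-outdegree sinks of the (sub)network.

    A node on a cycle is neither; an isolated node is both.
    """
    sources = {n for n in net.graph.nodes if net.graph.in_degree(n) == 0}
    sinks = {n for n in net.graph.nodes if net.graph.out_degree(n) == 0}
    return sources, sinks


def iter_simple_paths(
    net: RegulatoryNetwork,
    sources: Iterable[str],
    sinks: Iterable[str],
    max_len: int = 20,
) -> Iterator[RegulatoryPath]:
    """Yield every simple path from any source to any sink, each exactly once.

    Paths have at least 2 and at most ``max_len`` nodes.  Order is
    deterministic: sources ascending, then lexicographic by node id at each
    branch point (iterative depth-first expansion with an explicit stack).
    """
    if max_len < 2:
        raise ValueError("max_len must be >= 2 nodes")
    sink_set = set(sinks)
    graph = net.graph
    for source in sorted(set(sources) & set(graph.nodes)):
        # stack holds (path_tuple, on_path_set, iterator over successors)
        path = [source]
        on_path = {source}
        stack = [iter(sorted(graph.successors(source)))]
        while stack:
            children = stack[-1]
            nxt = next(children, None)
            if nxt is None:
                stack.pop()
                on_path.discard(path.pop())
                continue
            if nxt in on_path:
                continue
            path.append(nxt)
            on_path.add(nxt)
            if nxt in sink_set and len(path) >= 2:
                yield RegulatoryPath(tuple(path))
            if len(path) < max_len:
                stack.append(iter(sorted(graph.successors(nxt))))
            else:
                on_path.discard(path.pop())


def enumerate_paths(
    net: RegulatoryNetwork,
    sources: Iterable[str] | None = None,
    sinks: Iterable[str] | None = None,
    max_len: int = 20,
    max_paths: int = 1_000_000,
) -> PathSearchResult:
    """Collect all source-to-sink simple paths, bounded by length and count caps.

    ``sources``/``sinks`` default to the network's 0-indegree/0-outdegree
    terminals.  When ``max_paths`` is reached the search stops and the result
    is flagged truncated (a flagged condition, not an error).
    """
    if max_paths < 1:
        raise ValueError("max_paths must be >= 1")
    if sources is None or sinks is None:
        terminal_sources, terminal_sinks = find_terminals(net)
        sources = terminal_sources if sources is None else sources
        sinks = terminal_sinks if sinks is None else sinks
    result = PathSearchResult()
    for path in iter_simple_paths(net, sources, sinks, max_len=max_len):
        if len(result.paths) >= max_paths:
            result.truncated = True
            break
        result.paths.append(path)
    return result


def _is_gap(ann: NodeAnnotation) -> bool:
    # non-DE nodes and nodes without expression measurements both count
    # against the spacing rule
    return not ann.is_de or not ann.has_expression


def is_potential_active(
    path: RegulatoryPath,
    annotations: Mapping[str, NodeAnnotation],
    terminal_rule: str = "internal_only",
    min_de_nodes: int = 1,
) -> bool:
    """Decide whether one path qualifies as a potential active pathway.

    Requires (i) at least 3 nodes, (ii) at least ``min_de_nodes`` DE nodes,
    and (iii) every maximal run of consecutive inactive nodes (non-DE or
    unmeasured) lying strictly between two DE nodes to have length <= 1.
    Under ``terminal_rule="all_runs"`` the run-length constraint also applies
    to leading and trailing runs.
    """
    if terminal_rule not in ("internal_only", "all_runs"):
        raise ValueError(f"unknown terminal_rule {terminal_rule!r}")
    try:
        anns = [annotations[node] for node in path.nodes]
    except KeyError as exc:
        raise AnnotationMissingError(f"no annotation for node {exc.args[0]!r}") from None

    if len(path) < 3:
        return False
    de_flags = [not _is_gap(a) for a in anns]
    if sum(de_flags) < min_de_nodes:
        return False

    # scan maximal runs of inactive nodes
    i, n = 0, len(de_flags)
    while i < n:
        if de_flags[i]:
            i += 1
            continue
        j = i
        while j < n and not de_flags[j]:
            j += 1
        run_len = j - i
        internal = i > 0 and j < n  # bounded by DE nodes on both sides
        if run_len > 1 and (internal or terminal_rule == "all_runs"):
            return False
        i = j
    return True


def filter_potential_active(
    paths: Iterable[RegulatoryPath],
    annotations: Mapping[str, NodeAnnotation],
    terminal_rule: str = "internal_only",
    min_de_nodes: int = 1,
) -> list[RegulatoryPath]:
    """Keep the paths that qualify as potential active pathways."""
    return [
        p
        for p in paths
        if is_potential_active(p, annotations, terminal_rule, min_de_nodes)
    ]


def paths_to_rows(
    paths: Sequence[RegulatoryPath],
    annotations: Mapping[str, NodeAnnotation] | None = None,
    truncated: bool = False,
) -> list[dict]:
    """Rows for the path table: ``path  n_nodes  n_de  truncated_flag``."""
    rows = []
    for p in paths:
        n_de = (
            sum(1 for node in p.nodes if annotations[node].is_de)
            if annotations is not None
            else 0
        )
        rows.append(
            {
                "path": str(p),
                "n_nodes": len(p),
                "n_de": n_de,
                "truncated_flag": truncated,
            }
        )
    return rows
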