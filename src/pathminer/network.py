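"""Typed directed regulatory networks over miRNA, TF and gene nodes.

The curated network merges several edge resources (TF->gene, TF->miRNA,
miRNA->gene, miRNA->TF regulation).  Construction collapses redundant edges
between the same ordered node pair into a single edge whose provenance is the
union of the contributing resource labels, and drops self-loops outright.

Node classes are declared in the input edge lists, never inferred; an id
declared with two different classes is a hard error.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import networkx as nx

from .errors import ClassConflictError, EdgeListParseError

NODE_CLASSES = frozenset({"miRNA", "TF", "gene"})


class EdgeRow(NamedTuple):
    """One typed regulatory interaction from a single resource."""

    source: str
    source_class: str
    target: str
    target_class: str
    resource: str


@dataclass
class EdgeList:
    """An ordered list of typed edges, as read from one resource file."""

    rows: list[EdgeRow] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        for i, row in enumerate(self.rows):
            if not row.source or not row.target:
                raise EdgeListParseError(f"row {i}: empty node id")
            for cls in (row.source_class, row.target_class):
                if cls not in NODE_CLASSES:
                    raise EdgeListParseError(
                        f"row {i}: unknown node class {cls!r} "
                        f"(expected one of {sorted(NODE_CLASSES)})"
                    )

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[EdgeRow]:
        return iter(self.rows)


class RegulatoryNetwork:
    """A typed directed graph with unique, self-loop-free, provenance-tagged edges.

    Thin wrapper around a :class:`networkx.DiGraph` whose nodes carry a
    ``node_class`` attribute in {miRNA, TF, gene} and whose edges carry a
    ``provenance`` frozenset of resource labels.
    """

    def __init__(self, graph: nx.DiGraph):
        for node, data in graph.nodes(data=True):
            cls = data.get("node_class")
            if cls not in NODE_CLASSES:
                raise ValueError(f"node {node!r} has invalid node_class {cls!r}")
        for u, v in graph.edges():
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
        self.graph = graph

    # -- construction -----------------------------------------------------

    @classmethod
    def build(
        cls,
        classes: Mapping[str, str],
        edges: Iterable[tuple[str, str]] = (),
        provenance: str = "manual",
    ) -> "RegulatoryNetwork":
        """Construct a network from a node-class map and (source, target) pairs.

        Convenience constructor for small programmatic graphs; self-loops and
        duplicate pairs are rejected rather than silently collapsed.
        """
        g = nx.DiGraph()
        for node, node_cls in classes.items():
            g.add_node(node, node_class=node_cls)
        for u, v in edges:
            if u not in classes or v not in classes:
                raise ValueError(f"edge ({u!r}, {v!r}) references an undeclared node")
            if g.has_edge(u, v):
                raise ValueError(f"duplicate edge ({u!r}, {v!r})")
            g.add_edge(u, v, provenance=frozenset({provenance}))
        return cls(g)

    # -- basic queries ----------------------------------------------------

    @property
    def node_ids(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges())

    def node_class(self, node: str) -> str:
        return self.graph.nodes[node]["node_class"]

    def node_classes(self) -> dict[str, str]:
        return {n: d["node_class"] for n, d in self.graph.nodes(data=True)}

    def provenance(self, source: str, target: str) -> frozenset[str]:
        return self.graph.edges[source, target]["provenance"]

    def in_neighbors(self, node: str) -> set[str]:
        return set(self.graph.predecessors(node))

    def out_neighbors(self, node: str) -> set[str]:
        return set(self.graph.successors(node))

    def subgraph(self, nodes: Iterable[str]) -> "RegulatoryNetwork":
        """Induced subgraph on the given nodes (attributes preserved)."""
        return RegulatoryNetwork(nx.DiGraph(self.graph.subgraph(nodes)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return self.node_classes() == other.node_classes() and {
            e: self.provenance(*e) for e in self.edges
        } == {e: other.provenance(*e) for e in other.edges}

    def __repr__(self) -> str:
        return f"RegulatoryNetwork({self.n_nodes} nodes, {self.n_edges} edges)"

    # -- serialization ----------------------------------------------------

    def to_graphml(self, path: str | Path) -> None:
        g = nx.DiGraph()
        for node, data in self.graph.nodes(data=True):
            g.add_node(node, **data)
        for u, v, data in self.graph.edges(data=True):
            attrs = dict(data)
            attrs["provenance"] = ",".join(sorted(attrs.get("provenance", ())))
            g.add_edge(u, v, **attrs)
        nx.write_graphml(g, str(path))

    @classmethod
    def from_graphml(cls, path: str | Path) -> "RegulatoryNetwork":
        g = nx.read_graphml(str(path))
        out = nx.DiGraph()
        for node, data in g.nodes(data=True):
            out.add_node(node, node_class=data["node_class"])
        for u, v, data in g.edges(data=True):
            prov = data.get("provenance", "")
            out.add_edge(u, v, provenance=frozenset(p for p in prov.split(",") if p))
        return cls(out)

    def to_sif(self, sif_path: str | Path, class_path: str | Path | None = None) -> None:
        """Write SIF plus a sidecar node-class table (``<sif>.classes.tsv``)."""
        sif_path = Path(sif_path)
        if class_path is None:
            class_path = sif_path.with_suffix(sif_path.suffix + ".classes.tsv")
        with open(sif_path, "w") as fh:
            for u, v in sorted(self.edges):
                fh.write(f"{u}\tregulates\t{v}\n")
        with open(class_path, "w") as fh:
            for node in sorted(self.node_ids):
                fh.write(f"{node}\t{self.node_class(node)}\n")


def read_node_classes(path: str | Path) -> dict[str, str]:
    """Read a two-column ``id<TAB>class`` table, ``#`` comments allowed."""
    classes: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise EdgeListParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            node, cls = parts
            if cls not in NODE_CLASSES:
                raise EdgeListParseError(f"{path}:{lineno}: unknown node class {cls!r}")
            if node in classes and classes[node] != cls:
                raise ClassConflictError(
                    f"{path}:{lineno}: node {node!r} declared as both "
                    f"{classes[node]!r} and {cls!r}"
                )
            classes[node] = cls
    return classes


def read_edge_list(
    path: str | Path,
    dialect: str = "tsv",
    class_path: str | Path | None = None,
    resource: str | None = None,
) -> EdgeList:
    """Read a typed edge list.

    Parameters
    ----------
    path:
        Input file.  ``tsv`` dialect expects five tab-separated columns
        ``source source_class target target_class resource``; ``sif`` expects
        ``source interaction target`` with the interaction column used as the
        resource label and node classes supplied by a sidecar table.
    dialect:
        ``"tsv"`` or ``"sif"``.
    class_path:
        Node-class sidecar (required for ``sif``).
    resource:
        Overrides the resource label of every row when given.
    """
    path = Path(path)
    rows: list[EdgeRow] = []
    if dialect == "tsv":
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 5:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: expected 5 tab-separated columns, got {len(parts)}"
                    )
                src, src_cls, tgt, tgt_cls, res = (p.strip() for p in parts)
                for cls in (src_cls, tgt_cls):
                    if cls not in NODE_CLASSES:
                        raise EdgeListParseError(
                            f"{path}:{lineno}: unknown node class {cls!r}"
                        )
                if not src or not tgt:
                    raise EdgeListParseError(f"{path}:{lineno}: empty node id")
                rows.append(EdgeRow(src, src_cls, tgt, tgt_cls, resource or res))
    elif dialect == "sif":
        if class_path is None:
            raise ValueError("sif dialect requires a node-class sidecar (class_path)")
        classes = read_node_classes(class_path)
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) != 3:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: expected 3 columns (source interaction target)"
                    )
                src, interaction, tgt = parts
                for node in (src, tgt):
                    if node not in classes:
                        raise EdgeListParseError(
                            f"{path}:{lineno}: node {node!r} missing from class sidecar"
                        )
                rows.append(
                    EdgeRow(src, classes[src], tgt, classes[tgt], resource or interaction)
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'sif')")
    return EdgeList(rows=rows, name=path.stem)


def write_edge_list(edge_list: EdgeList, path: str | Path) -> None:
    """Write the five-column TSV dialect."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for row in edge_list.rows:
            writer.writerow(row)


def merge_edge_lists(lists: Sequence[EdgeList]) -> RegulatoryNetwork:
    """Merge typed edge lists into one deduplicated regulatory network.

    Redundant edges between the same ordered node pair collapse to a single
    edge whose provenance is the union of the contributing resource labels;
    self-directed edges are deleted (their endpoints are retained as nodes).

    Raises
    ------
    ClassConflictError
        If a node id appears with two different node classes.
    """
    classes: dict[str, str] = {}
    edges: dict[tuple[str, str], set[str]] = {}

    def declare(node: str, cls: str) -> None:
        if node in classes and classes[node] != cls:
            raise ClassConflictError(
                f"node {node!r} declared as both {classes[node]!r} and {cls!r}"
            )
        classes[node] = cls

    for lst in lists:
        for row in lst:
            declare(row.source, row.source_class)
            declare(row.target, row.target_class)
            if row.source == row.target:
                continue  # self-loop: node kept, edge dropped
            edges.setdefault((row.source, row.target), set()).add(row.resource)

    g = nx.DiGraph()
    for node, cls in classes.items():
        g.add_node(node, node_class=cls)
    for (u, v), prov in edges.items():
        g.add_edge(u, v, provenance=frozenset(prov))
    return RegulatoryNetwork(g)
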