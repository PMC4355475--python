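"""Active-subnetwork extraction around differentially expressed seed nodes.

Differentially expressed genes and miRNAs are mapped onto the curated
regulatory network as seeds; the potential active subnetwork keeps the seeds
together with their immediate neighbors (both regulators and targets), since
disease-relevant hubs can themselves sit just outside the DE set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from .network import RegulatoryNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NodeAnnotation:
    """Per-node flags used by pathway filtering and reporting.

    ``is_de`` implies ``has_expression``: a feature can only be called
    differentially expressed if it was measured.
    """

    node: str
    is_de: bool
    has_expression: bool
    is_known_disease: bool

    def __post_init__(self) -> None:
        if self.is_de and not self.has_expression:
            raise ValueError(f"node {self.node!r}: is_de requires has_expression")


def extract_active_subnetwork(
    net: RegulatoryNetwork,
    seeds: Iterable[str],
    edge_policy: str = "induced",
) -> RegulatoryNetwork:
    """Seeds plus their immediate neighbors, with connecting edges.

    The node set is the seeds together with all their in- and out-neighbors.
    Under the default ``induced`` policy the edge set is every network edge
    with both endpoints retained (neighbor-neighbor edges kept); under
    ``star`` only edges incident to a seed are kept.  Seed ids absent from
    the network are dropped with a warning.
    """
    if edge_policy not in ("induced", "star"):
        raise ValueError(f"unknown edge_policy {edge_policy!r}")
    seeds = set(seeds)
    present = seeds & net.node_ids
    dropped = len(seeds) - len(present)
    if dropped:
        logger.warning("%d seed id(s) not present in the network were dropped", dropped)
    if not present:
        logger.warning("empty seed set: returning an empty subnetwork")
        return RegulatoryNetwork(nx.DiGraph())

    keep = set(present)
    for seed in present:
        keep |= net.in_neighbors(seed)
        keep |= net.out_neighbors(seed)

    sub = net.subgraph(keep)
    if edge_policy == "star":
        g = nx.DiGraph()
        for node in keep:
            g.add_node(node, node_class=net.node_class(node))
        for u, v in sub.edges:
            if u in present or v in present:
                g.add_edge(u, v, provenance=net.provenance(u, v))
        sub = RegulatoryNetwork(g)
    return sub


def annotate_nodes(
    net: RegulatoryNetwork,
    de_set: Iterable[str],
    expressed_set: Iterable[str],
    known_set: Iterable[str],
) -> dict[str, NodeAnnotation]:
    """Annotate every network node by set membership.

    A node flagged DE is treated as measured even if missing from
    ``expressed_set``, preserving the is_de => has_expression invariant.
    """
    de = set(de_set)
    expressed = set(expressed_set) | de
    known = set(known_set)
    return {
        node: NodeAnnotation(
            node=node,
            is_de=node in de,
            has_expression=node in expressed,
            is_known_disease=node in known,
        )
        for node in net.node_ids
    }
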