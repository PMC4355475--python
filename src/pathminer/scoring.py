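"""Coverage-rate scoring of regulatory paths against a known disease list.

Each candidate path is scored by its coverage rate CR = N_D / N_T, the
fraction of its nodes that belong to a curated disease-associated list.
Significance is the upper-tail hypergeometric probability of drawing at
least N_D known nodes in N_T draws without replacement from a background
population of N nodes of which K are known, followed by Benjamini-Hochberg
adjustment across all candidate paths.  Paths whose adjusted q-value falls
below the configured threshold form the active set; their union graph merges
identical nodes across paths.

The default background population is the set of distinct nodes appearing in
any candidate path.  Because published analyses of this kind rarely state
their background explicitly, both N and K can be overridden.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .network import RegulatoryNetwork
from .paths import RegulatoryPath

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Background:
    """Hypergeometric background: N eligible nodes, K of them disease-associated."""

    population_size: int
    known_in_population: int

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if not 0 <= self.known_in_population <= self.population_size:
            raise ValueError("require 0 <= K <= N")

    @classmethod
    def from_paths(
        cls, paths: Iterable[RegulatoryPath], known_set: Iterable[str]
    ) -> "Background":
        """In-pathway background: all distinct path nodes; K = known among them."""
        population: set[str] = set()
        for path in paths:
            population.update(path.nodes)
        known = population & set(known_set)
        if not population:
            raise ValueError("cannot derive a background from zero paths")
        return cls(population_size=len(population), known_in_population=len(known))


@dataclass(frozen=True)
class PathwayScore:
    """Score record for one candidate path."""

    path: RegulatoryPath
    n_known: int  # N_D
    n_total: int  # N_T
    coverage: float  # CR = N_D / N_T
    p_value: float
    q_value: float
    active: bool


def coverage_rate(n_known: int, n_total: int) -> float:
    """Coverage rate CR = N_D / N_T of known disease nodes in a path.

    Raises
    ------
    ValueError
        If ``n_total`` < 1 or ``n_known`` is outside [0, n_total].
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_known <= n_total:
        raise ValueError("require 0 <= n_known <= n_total")
    return n_known / n_total


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Probability of observing at least ``k`` known nodes when drawing ``n``
    nodes without replacement from a population of ``N`` containing ``K``
    known nodes.  Evaluated in log space, stable for N up to ~1e5.
    """
    if not (0 <= K <= N):
        raise ValueError("require 0 <= K <= N")
    if not (0 <= k <= n <= N):
        raise ValueError("require 0 <= k <= n <= N")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X > k-1) = P(X >= k)
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def score_pathways(
    paths: Sequence[RegulatoryPath],
    known_set: Iterable[str],
    background: Background | None = None,
    fdr_threshold: float = 0.0005,
) -> tuple[list[PathwayScore], list[PathwayScore]]:
    """Score candidate paths and select the active subset.

    Each path is scored with draws n = N_T (its distinct node count) and
    observed k = N_D (its known-node count) against the background; q-values
    are Benjamini-Hochberg over all candidate paths, and the active subset is
    ``{q < fdr_threshold}``.  Scores are returned sorted by
    (q, p, -CR, path string) for full determinism.

    Returns
    -------
    (scores, active):
        All scores, and the active subset (same objects, same order).
    """
    known = set(known_set)
    paths = list(paths)
    if not paths:
        return [], []
    if background is None:
        background = Background.from_paths(paths, known)
    if background.known_in_population == 0:
        warnings.warn(
            "known set is disjoint from the background population; all p-values are 1",
            stacklevel=2,
        )

    n_known = [sum(1 for node in path.nodes if node in known) for path in paths]
    n_total = [len(path) for path in paths]
    p_values = [
        hypergeom_tail(
            background.population_size, background.known_in_population, n, k
        )
        for n, k in zip(n_total, n_known)
    ]
    q_values = bh_fdr(p_values)

    scores = [
        PathwayScore(
            path=path,
            n_known=k,
            n_total=n,
            coverage=coverage_rate(k, n),
            p_value=p,
            q_value=float(q),
            active=bool(q < fdr_threshold),
        )
        for path, k, n, p, q in zip(paths, n_known, n_total, p_values, q_values)
    ]
    scores.sort(key=lambda s: (s.q_value, s.p_value, -s.coverage, s.path.nodes))
    active = [s for s in scores if s.active]
    logger.info("scored %d paths, %d active at q < %g", len(scores), len(active), fdr_threshold)
    return scores, active


def scores_to_frame(scores: Sequence[PathwayScore]) -> pd.DataFrame:
    """Tabulate scores: ``path  N_D  N_T  CR  p_value  q_value  active``."""
    return pd.DataFrame(
        {
            "path": [" -> ".join(s.path.nodes) for s in scores],
            "N_D": [s.n_known for s in scores],
            "N_T": [s.n_total for s in scores],
            "CR": [s.coverage for s in scores],
            "p_value": [s.p_value for s in scores],
            "q_value": [s.q_value for s in scores],
            "active": [s.active for s in scores],
        }
    )


def union_graph(
    paths: Iterable[RegulatoryPath],
    net: RegulatoryNetwork | None = None,
    provenance: str = "active_pathway",
) -> RegulatoryNetwork:
    """Merge paths into one graph: identical nodes collapse, edges are unioned.

    Node classes are carried over from ``net`` when given; otherwise every
    node defaults to class ``gene``.
    """
    classes: Mapping[str, str] = net.node_classes() if net is not None else {}
    g = nx.DiGraph()
    for path in paths:
        for node in path.nodes:
            g.add_node(node, node_class=classes.get(node, "gene"))
        for u, v in zip(path.nodes, path.nodes[1:]):
            if net is not None and (u, v) in net.edges:
                prov = net.provenance(u, v)
            else:
                prov = frozenset({provenance})
            g.add_edge(u, v, provenance=prov)
    return RegulatoryNetwork(g)
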