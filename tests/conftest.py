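import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pathminer.network import RegulatoryNetwork

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


def build_net(classes: dict[str, str], edges) -> RegulatoryNetwork:
    """Shorthand network builder used throughout the suite."""
    return RegulatoryNetwork.build(classes, edges)


def chain_net(*nodes: str, cls: str = "TF") -> RegulatoryNetwork:
    """A -> B -> C ... chain with a uniform node class."""
    return build_net({n: cls for n in nodes}, list(zip(nodes, nodes[1:])))


@pytest.fixture
def small_dataset():
    """4 control + 4 case samples, 3 features, fixed values."""
    from pathminer.diffexpr import ExpressionDataset

    rng = np.random.default_rng(11)
    samples = [f"s{i}" for i in range(8)]
    values = pd.DataFrame(
        rng.normal(8, 1, size=(3, 8)), index=["f1", "f2", "f3"], columns=samples
    )
    groups = pd.Series(["control"] * 4 + ["case"] * 4, index=samples)
    return ExpressionDataset(values=values, groups=groups, platform="T")


# ---------------------------------------------------------------------------
# independent oracles (kept free of the implementation they check)


def dfs_simple_paths(edges: set[tuple[str, str]], sources, sinks, max_len=10**9):
    """Recursive exhaustive simple-path search, coded independently."""
    adjacency: dict[str, list[str]] = {}
    for u, v in edges:
        adjacency.setdefault(u, []).append(v)
    out = set()

    def walk(node, path):
        if node in sinks and len(path) >= 2:
            out.add(tuple(path))
        if len(path) >= max_len:
            return
        for nxt in adjacency.get(node, []):
            if nxt not in path:
                walk(nxt, path + [nxt])

    for s in sources:
        walk(s, [s])
    return out


def dag_path_count(edges: set[tuple[str, str]], sources, sinks) -> int:
    """Dynamic-programming count of source->sink paths on a DAG."""
    from functools import lru_cache

    adjacency: dict[str, list[str]] = {}
    for u, v in edges:
        adjacency.setdefault(u, []).append(v)

    @lru_cache(maxsize=None)
    def count(node):
        total = 1 if node in sinks else 0
        for nxt in adjacency.get(node, []):
            total += count(nxt)
        return total

    # a source that is itself a sink contributes no (>= 2 node) path
    return sum(count(s) for s in sources if s not in sinks)


def exact_hypergeom_tail(N: int, K: int, n: int, k: int):
    """P(X >= k) as an exact rational via big-integer combinatorics."""
    from fractions import Fraction
    from math import comb

    total = comb(N, n)
    favorable = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return Fraction(favorable, total)
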