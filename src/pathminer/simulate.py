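"""Synthetic regulatory networks and expression studies with planted truth.

The generator emulates the structure of a two-group (control vs case)
microarray study paired with a curated typed regulatory network:

* a random directed network over miRNA, TF and gene nodes in which genes are
  pure targets (allowed edge types: TF->gene, TF->miRNA, miRNA->gene,
  miRNA->TF);
* a planted regulatory cascade — a chain of alternating miRNA/TF nodes
  ending in a gene — whose head has indegree 0 and whose tail has
  outdegree 0, so it must appear among source-to-sink paths;
* a known disease list containing the planted nodes plus random off-path
  contaminants, so coverage-rate scoring faces a non-degenerate background;
* probe-level log-intensity matrices for several mRNA platforms (1-3 probes
  per gene per platform) and a single miRNA matrix, with Gaussian noise and
  a mean shift of ``effect_size * noise_sd`` for planted DE features in the
  case group; a configurable fraction of network nodes receives no
  expression rows at all.

Everything is a pure function of the spec: the same spec (including its
seed) reproduces identical data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .diffexpr import ExpressionDataset, write_expression
from .errors import GenerationError
from .network import EdgeList, EdgeRow, RegulatoryNetwork, write_edge_list
from .paths import RegulatoryPath

# edge types of the curated-network model: (source class, target class, label)
EDGE_TYPES = (
    ("TF", "gene", "sim-tf-gene"),
    ("TF", "miRNA", "sim-tf-mirna"),
    ("miRNA", "gene", "sim-mirna-gene"),
    ("miRNA", "TF", "sim-mirna-tf"),
)

PLANTED_RESOURCE = "planted"


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults mirror a mid-size curated network and the two-group,
    multi-platform array design the pipeline targets: 20 control and 19 case
    samples profiled on 6 probe-level mRNA platforms plus one miRNA
    platform, a planted 9-node cascade whose nodes all appear in the known
    disease list, and moderate (2 noise-SD) case-group shifts for planted DE
    features.
    """

    n_tf: int = 25
    n_mirna: int = 18
    n_gene: int = 150
    density_tf_gene: float = 0.02
    density_tf_mirna: float = 0.03
    density_mirna_gene: float = 0.02
    density_mirna_tf: float = 0.03
    n_control: int = 20
    n_case: int = 19
    n_platforms: int = 6
    de_fraction: float = 0.1
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline: float = 8.0
    planted_path_len: int = 9
    known_list_size: int = 12
    planted_known_fraction: float = 1.0
    unmeasured_fraction: float = 0.05
    max_probes_per_gene: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tf", "n_mirna", "n_gene", "n_control", "n_case", "n_platforms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in (
            "density_tf_gene",
            "density_tf_mirna",
            "density_mirna_gene",
            "density_mirna_tf",
            "de_fraction",
            "unmeasured_fraction",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.planted_path_len < 3:
            raise ValueError("planted_path_len must be >= 3")
        if not 0.5 <= self.planted_known_fraction <= 1.0:
            raise ValueError("planted_known_fraction must lie in [0.5, 1]")
        if self.known_list_size < 1:
            raise ValueError("known_list_size must be positive")
        if self.max_probes_per_gene < 1:
            raise ValueError("max_probes_per_gene must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        return cls(**d)


@dataclass
class SyntheticStudy:
    """One fully generated study, including its ground truth."""

    spec: SyntheticSpec
    network: RegulatoryNetwork
    planted_path: RegulatoryPath
    known_set: set[str]
    planted_de: set[str]
    unmeasured: set[str]
    mrna: list[ExpressionDataset] = field(default_factory=list)
    mirna: ExpressionDataset | None = None


def _node_ids(spec: SyntheticSpec) -> dict[str, list[str]]:
    return {
        "TF": [f"TF{i:03d}" for i in range(1, spec.n_tf + 1)],
        "miRNA": [f"mir-{i:03d}" for i in range(1, spec.n_mirna + 1)],
        "gene": [f"G{i:03d}" for i in range(1, spec.n_gene + 1)],
    }


def generate_network(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> RegulatoryNetwork:
    """Random typed directed network respecting edge-type class constraints.

    Genes never act as sources; self-loops cannot arise because every edge
    type crosses classes.  Deterministic given ``spec`` (and ``rng`` state).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    pools = _node_ids(spec)
    densities = {
        ("TF", "gene"): spec.density_tf_gene,
        ("TF", "miRNA"): spec.density_tf_mirna,
        ("miRNA", "gene"): spec.density_mirna_gene,
        ("miRNA", "TF"): spec.density_mirna_tf,
    }
    g = nx.DiGraph()
    for cls, ids in pools.items():
        for node in ids:
            g.add_node(node, node_class=cls)
    for src_cls, tgt_cls, label in EDGE_TYPES:
        density = densities[(src_cls, tgt_cls)]
        srcs, tgts = pools[src_cls], pools[tgt_cls]
        draws = rng.random((len(srcs), len(tgts)))
        for i, u in enumerate(srcs):
            for j, v in enumerate(tgts):
                if u != v and draws[i, j] < density:
                    g.add_edge(u, v, provenance=frozenset({label}))
    return RegulatoryNetwork(g)


def _planted_classes(length: int) -> list[str]:
    """Alternating miRNA/TF chain ending in a gene sink."""
    classes = ["miRNA" if i % 2 == 0 else "TF" for i in range(length - 1)]
    classes.append("gene")
    return classes


def plant_active_pathway(
    net: RegulatoryNetwork,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> tuple[RegulatoryNetwork, RegulatoryPath, set[str]]:
    """Insert a ground-truth cascade and build the known disease list.

    The chain alternates miRNA and TF nodes and ends at a gene; background
    edges into its head and out of its tail are removed so the head is a
    0-indegree source and the tail a 0-outdegree sink.  At least half (by
    default all) of the planted nodes enter the known list, which is then
    topped up with random non-path nodes.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    classes = _planted_classes(spec.planted_path_len)
    by_class = {"miRNA": [], "TF": [], "gene": []}
    node_classes = net.node_classes()
    for node in sorted(net.node_ids):
        by_class[node_classes[node]].append(node)
    chain: list[str] = []
    used: set[str] = set()
    for cls in classes:
        avail = [n for n in by_class[cls] if n not in used]
        if not avail:
            raise GenerationError(
                f"not enough {cls} nodes to embed a planted path of length "
                f"{spec.planted_path_len}; increase n_{cls.lower() if cls != 'miRNA' else 'mirna'}"
            )
        pick = avail[int(rng.integers(len(avail)))]
        chain.append(pick)
        used.add(pick)

    g = nx.DiGraph(net.graph)
    for u, v in zip(chain, chain[1:]):
        prov = set(g.edges[u, v]["provenance"]) if g.has_edge(u, v) else set()
        prov.add(PLANTED_RESOURCE)
        g.add_edge(u, v, provenance=frozenset(prov))
    # enforce terminal degree conditions
    for pred in list(g.predecessors(chain[0])):
        g.remove_edge(pred, chain[0])
    for succ in list(g.successors(chain[-1])):
        g.remove_edge(chain[-1], succ)

    planted = RegulatoryPath(tuple(chain))
    n_known_on_path = max(
        math.ceil(spec.planted_known_fraction * len(chain)),
        math.ceil(len(chain) / 2),
    )
    order = rng.permutation(len(chain))
    known = {chain[i] for i in order[:n_known_on_path]}
    off_path = [n for n in sorted(net.node_ids) if n not in set(chain)]
    n_fill = max(0, spec.known_list_size - len(known))
    fill_idx = rng.permutation(len(off_path))[:n_fill]
    known |= {off_path[i] for i in fill_idx}
    return RegulatoryNetwork(g), planted, known


def generate_expression(
    net: RegulatoryNetwork,
    planted_de: Iterable[str],
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    unmeasured: Iterable[str] = (),
) -> tuple[list[ExpressionDataset], ExpressionDataset]:
    """Probe-level mRNA platforms plus one miRNA matrix.

    Control values are Normal(baseline, noise_sd); case values of planted DE
    features are shifted by ``effect_size * noise_sd``.  Genes and TFs are
    measured on every mRNA platform through 1-3 probes each; miRNAs form a
    single feature-level matrix.  Nodes listed in ``unmeasured`` receive no
    rows anywhere.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    planted_de = set(planted_de)
    unmeasured = set(unmeasured)
    missing = planted_de & unmeasured
    if missing:
        raise ValueError(f"planted DE nodes cannot be unmeasured: {sorted(missing)}")

    node_classes = net.node_classes()
    mrna_features = sorted(
        n for n, c in node_classes.items() if c in ("gene", "TF") and n not in unmeasured
    )
    mirna_features = sorted(
        n for n, c in node_classes.items() if c == "miRNA" and n not in unmeasured
    )
    samples = [f"C{i:02d}" for i in range(1, spec.n_control + 1)] + [
        f"O{i:02d}" for i in range(1, spec.n_case + 1)
    ]
    groups = pd.Series(
        ["control"] * spec.n_control + ["case"] * spec.n_case, index=samples
    )
    case = (groups == "case").to_numpy()
    shift = spec.effect_size * spec.noise_sd

    def matrix(features: Sequence[str], n_rows_per_feature: Sequence[int]):
        rows, index = [], []
        for feat, n_rows in zip(features, n_rows_per_feature):
            mu = np.full(len(samples), spec.baseline)
            if feat in planted_de:
                mu = mu + shift * case
            for k in range(n_rows):
                rows.append(mu + rng.normal(0.0, spec.noise_sd, size=len(samples)))
                index.append((feat, k))
        return rows, index

    platforms: list[ExpressionDataset] = []
    for p in range(1, spec.n_platforms + 1):
        tag = f"P{p}"
        n_probes = rng.integers(1, spec.max_probes_per_gene + 1, size=len(mrna_features))
        rows, index = matrix(mrna_features, n_probes)
        probe_ids = [f"{tag}:{feat}:probe{k + 1}" for feat, k in index]
        values = pd.DataFrame(np.array(rows), index=probe_ids, columns=samples)
        probe_map = pd.Series([feat for feat, _ in index], index=probe_ids)
        platforms.append(
            ExpressionDataset(
                values=values, groups=groups.copy(), platform=tag, probe_map=probe_map
            )
        )

    rows, index = matrix(mirna_features, [1] * len(mirna_features))
    mirna_values = pd.DataFrame(
        np.array(rows), index=[feat for feat, _ in index], columns=samples
    )
    mirna = ExpressionDataset(
        values=mirna_values, groups=groups.copy(), platform="miRNA", probe_map=None
    )
    return platforms, mirna


def simulate_study(spec: SyntheticSpec) -> SyntheticStudy:
    """Generate network, planted truth, known list and expression in one pass."""
    rng = np.random.default_rng(spec.seed)
    net = generate_network(spec, rng)
    net, planted_path, known = plant_active_pathway(net, spec, rng)

    planted_nodes = set(planted_path.nodes)
    others = [n for n in sorted(net.node_ids) if n not in planted_nodes]
    n_extra_de = round(spec.de_fraction * len(others))
    order = rng.permutation(len(others))
    extra_de = {others[i] for i in order[:n_extra_de]}
    planted_de = planted_nodes | extra_de

    eligible = [n for n in others if n not in planted_de]
    n_unmeasured = round(spec.unmeasured_fraction * net.n_nodes)
    order = rng.permutation(len(eligible))
    unmeasured = {eligible[i] for i in order[:n_unmeasured]}

    mrna, mirna = generate_expression(net, planted_de, spec, rng, unmeasured=unmeasured)
    return SyntheticStudy(
        spec=spec,
        network=net,
        planted_path=planted_path,
        known_set=known,
        planted_de=planted_de,
        unmeasured=unmeasured,
        mrna=mrna,
        mirna=mirna,
    )


def generate_dataset(
    n_features: int = 500,
    n_control: int = 10,
    n_case: int = 10,
    de_fraction: float = 0.0,
    effect_size: float = 0.0,
    noise_sd: float = 1.0,
    baseline: float = 8.0,
    seed: int = 0,
    platform: str = "sim",
) -> tuple[ExpressionDataset, set[str]]:
    """Flat two-group matrix with planted DE features (no network attached).

    Used for calibration studies of the DE statistic itself.  The first
    ``round(de_fraction * n_features)`` features are shifted by
    ``effect_size * noise_sd`` in the case group.  Returns the dataset and
    the set of planted DE feature ids.
    """
    rng = np.random.default_rng(seed)
    features = [f"F{i:04d}" for i in range(1, n_features + 1)]
    n_de = round(de_fraction * n_features)
    planted = set(features[:n_de])
    samples = [f"C{i:02d}" for i in range(1, n_control + 1)] + [
        f"O{i:02d}" for i in range(1, n_case + 1)
    ]
    groups = pd.Series(["control"] * n_control + ["case"] * n_case, index=samples)
    case = (groups == "case").to_numpy()
    X = rng.normal(baseline, noise_sd, size=(n_features, len(samples)))
    X[:n_de, case] += effect_size * noise_sd
    values = pd.DataFrame(X, index=features, columns=samples)
    return (
        ExpressionDataset(values=values, groups=groups, platform=platform),
        planted,
    )


def network_to_edge_list(net: RegulatoryNetwork) -> EdgeList:
    """Flatten a network into one five-column edge list (one row per resource).

    Isolated nodes are written as self-directed rows: the merge step deletes
    the self-loop but retains the node, so the flattened list reconstructs
    the network exactly.
    """
    classes = net.node_classes()
    rows = []
    connected: set[str] = set()
    for u, v in sorted(net.edges):
        connected.update((u, v))
        for resource in sorted(net.provenance(u, v)):
            rows.append(EdgeRow(u, classes[u], v, classes[v], resource))
    for node in sorted(net.node_ids - connected):
        rows.append(EdgeRow(node, classes[node], node, classes[node], "isolated"))
    return EdgeList(rows=rows, name="network")


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict:
    """Write a study to disk as plain-text fixtures; returns the file map.

    Layout: one merged edge-list TSV, per-platform expression and probe-map
    TSVs, a miRNA expression TSV, shared label sidecars, the known list, and
    a ground-truth manifest (planted path, planted DE ids) in YAML.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict = {"out_dir": str(out)}

    edges_path = out / "edges.tsv"
    write_edge_list(network_to_edge_list(study.network), edges_path)
    files["edges"] = str(edges_path)

    files["mrna"] = []
    for ds in study.mrna:
        v = out / f"expr_{ds.platform}.tsv"
        l = out / f"labels_{ds.platform}.tsv"
        m = out / f"probes_{ds.platform}.tsv"
        write_expression(ds, v, l, m)
        files["mrna"].append(
            {"values": str(v), "labels": str(l), "probe_map": str(m), "platform": ds.platform}
        )
    if study.mirna is not None:
        v = out / "expr_miRNA.tsv"
        l = out / "labels_miRNA.tsv"
        write_expression(study.mirna, v, l)
        files["mirna"] = {"values": str(v), "labels": str(l), "platform": "miRNA"}

    known_path = out / "known.txt"
    with open(known_path, "w") as fh:
        fh.write("# known disease-associated nodes\n")
        for node in sorted(study.known_set):
            fh.write(node + "\n")
    files["known"] = str(known_path)

    manifest = {
        "spec": study.spec.to_dict(),
        "planted_path": list(study.planted_path.nodes),
        "planted_de": sorted(study.planted_de),
        "known_set": sorted(study.known_set),
        "unmeasured": sorted(study.unmeasured),
    }
    manifest_path = out / "truth.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    files["truth"] = str(manifest_path)
    return files


def read_known_list(path: str | Path) -> set[str]:
    """One node id per line, ``#`` comments allowed."""
    known: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                known.add(line)
    return known
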