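"""Dense-subcluster detection (MCODE) and hub identification on module graphs.

The MCODE algorithm is implemented from its published definition: each node
is weighted by the density of the highest k-core of its closed neighbourhood
times that core's order; complexes grow outward from unvisited highest-weight
seeds admitting neighbours whose weight exceeds a fraction of the seed
weight, are required to contain a k-core, and are optionally "haircut" of
singly-connected members.  Hubs are nodes whose degree strictly exceeds the
90th percentile (nearest rank) of their module's degree distribution, with a
degree-vs-betweenness correlation reported as a centrality diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Subcluster",
    "HubSet",
    "graph_from_edges",
    "module_graphs",
    "mcode_vertex_weight",
    "mcode_complexes",
    "betweenness_centrality",
    "find_hubs",
]


@dataclass
class Subcluster:
    """A dense complex found by MCODE."""

    members: list[str]
    seed: str
    score: float  # density x size

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class HubSet:
    """Per-module hub calls and the degree-betweenness diagnostic."""

    table: pd.DataFrame  # gene, module, degree, betweenness, is_hub
    degree_cutoffs: dict[str, float] = field(default_factory=dict)
    degree_betweenness_cor: dict[str, float] = field(default_factory=dict)

    def hubs(self, module: str | None = None) -> list[str]:
        t = self.table[self.table["is_hub"]]
        if module is not None:
            t = t[t["module"] == module]
        return list(t["gene"])


def graph_from_edges(edges: pd.DataFrame) -> nx.Graph:
    """Undirected simple graph from an exported edge table."""
    g = nx.Graph()
    g.add_edges_from(zip(edges["gene_a"], edges["gene_b"]))
    return g


def module_graphs(edges: pd.DataFrame) -> dict[str, nx.Graph]:
    """One graph per module from an exported edge table."""
    out = {}
    for module, part in edges.groupby("module"):
        g = nx.Graph()
        g.add_edges_from(zip(part["gene_a"], part["gene_b"]))
        out[module] = g
    return out


def mcode_vertex_weight(graph: nx.Graph, node) -> float:
    """Highest-core order times that core's density on the closed neighbourhood."""
    if node not in graph:
        raise KeyError(f"node {node!r} not in graph")
    nbhd = list(graph.neighbors(node))
    if not nbhd:
        return 0.0
    sub = graph.subgraph([node, *nbhd])
    cores = nx.core_number(sub)
    k = max(cores.values())
    if k == 0:
        return 0.0
    core = sub.subgraph([n for n, c in cores.items() if c >= k])
    return float(k) * nx.density(core)


def _haircut(graph: nx.Graph, members: set) -> set:
    """Iteratively strip members with degree <= 1 inside the complex."""
    members = set(members)
    while True:
        sub = graph.subgraph(members)
        drop = {n for n in members if sub.degree(n) <= 1}
        if not drop or drop == members:
            return members - drop if drop != members else set()
        members -= drop


def mcode_complexes(
    graph: nx.Graph,
    degree_cutoff: int = 2,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    max_depth: int = 100,
    haircut: bool = True,
    fluff: bool = False,
) -> list[Subcluster]:
    """MCODE complex prediction with the standard default parameters.

    Nodes below ``degree_cutoff`` are not used as seeds; growth from a seed
    admits unvisited neighbours whose weight is strictly greater than
    ``(1 - node_score_cutoff) * seed_weight`` up to ``max_depth`` steps from
    the seed; complexes that do not contain a ``k_core``-core are discarded
    and the haircut strips singly-connected members.  Ties between equal
    seed weights break on the lexicographically smallest node id, making the
    output deterministic.
    """
    if fluff:
        raise NotImplementedError("fluff post-processing is not provided")
    if graph.number_of_nodes() == 0:
        return []
    weights = {n: mcode_vertex_weight(graph, n) for n in graph.nodes}
    order = sorted(graph.nodes, key=lambda n: (-weights[n], str(n)))
    visited: set = set()
    complexes: list[Subcluster] = []
    for seed in order:
        if seed in visited or graph.degree(seed) < degree_cutoff:
            continue
        threshold = (1.0 - node_score_cutoff) * weights[seed]
        members = {seed}
        visited.add(seed)
        frontier = [seed]
        depth = 0
        while frontier and depth < max_depth:
            nxt = []
            for u in frontier:
                for v in sorted(graph.neighbors(u), key=str):
                    if v in visited:
                        continue
                    if weights[v] > threshold:
                        visited.add(v)
                        members.add(v)
                        nxt.append(v)
            frontier = nxt
            depth += 1
        sub = graph.subgraph(members)
        cores = nx.core_number(sub) if sub.number_of_edges() else {n: 0 for n in members}
        if not cores or max(cores.values()) < k_core:
            continue
        if haircut:
            members = _haircut(graph, members)
            if not members:
                continue
        sub = graph.subgraph(members)
        score = nx.density(sub) * len(members)
        complexes.append(
            Subcluster(members=sorted(members, key=str), seed=seed, score=score)
        )
    complexes.sort(key=lambda c: (-c.score, c.members))
    return complexes


def betweenness_centrality(graph: nx.Graph) -> dict:
    """Unnormalised shortest-path betweenness (per connected component)."""
    return nx.betweenness_centrality(graph, normalized=False)


def _nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th smallest value."""
    v = np.sort(np.asarray(values))
    rank = int(np.ceil(percentile / 100.0 * v.size))
    rank = min(max(rank, 1), v.size)
    return float(v[rank - 1])


def find_hubs(
    edges: pd.DataFrame,
    percentile: float = 90.0,
    min_module_nodes: int = 10,
    per_module: bool = True,
) -> HubSet:
    """Hubs: nodes whose degree strictly exceeds the percentile cutoff.

    By default the cutoff is the nearest-rank percentile of each module's own
    degree distribution (a global mode pools all modules).  Modules with
    fewer than ``min_module_nodes`` nodes yield no hubs and a warning.  The
    Pearson correlation of degree vs betweenness per module is reported and
    a non-positive value triggers a warning.
    """
    graphs = module_graphs(edges)
    rows = []
    cutoffs: dict[str, float] = {}
    cors: dict[str, float] = {}
    if not per_module:
        all_degrees = np.concatenate(
            [np.array([d for _, d in g.degree()]) for g in graphs.values()]
        ) if graphs else np.array([])
        global_cutoff = (
            _nearest_rank_percentile(all_degrees, percentile)
            if all_degrees.size else np.inf
        )
    for module, g in sorted(graphs.items()):
        degree = dict(g.degree())
        btw = betweenness_centrality(g)
        nodes = sorted(g.nodes, key=str)
        deg_arr = np.array([degree[n] for n in nodes], dtype=float)
        if per_module:
            cutoff = _nearest_rank_percentile(deg_arr, percentile)
        else:
            cutoff = global_cutoff
        too_small = len(nodes) < min_module_nodes
        if too_small:
            warnings.warn(
                f"module {module} has {len(nodes)} nodes (<{min_module_nodes}); "
                "no hubs called",
                RuntimeWarning,
                stacklevel=2,
            )
        btw_arr = np.array([btw[n] for n in nodes], dtype=float)
        if deg_arr.std() > 0 and btw_arr.std() > 0:
            cor = float(np.corrcoef(deg_arr, btw_arr)[0, 1])
        else:
            cor = float("nan")
        if cor <= 0:
            warnings.warn(
                f"module {module}: degree-betweenness correlation {cor:.3f} <= 0",
                RuntimeWarning,
                stacklevel=2,
            )
        cutoffs[module] = cutoff
        cors[module] = cor
        for n in nodes:
            rows.append({
                "gene": n,
                "module": module,
                "degree": degree[n],
                "betweenness": btw[n],
                "is_hub": (not too_small) and degree[n] > cutoff,
            })
    table = pd.DataFrame(
        rows, columns=["gene", "module", "degree", "betweenness", "is_hub"]
    )
    return HubSet(table=table, degree_cutoffs=cutoffs, degree_betweenness_cor=cors)
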