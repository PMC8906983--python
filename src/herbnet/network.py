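"""Interaction graphs and node-centrality analysis.

Two graphs drive the analysis:

* the **PPI network** — an undirected protein-protein interaction graph built
  from a STRING-style scored edge list, thresholded on the combined
  confidence score (medium confidence, 0.400, by default) with free nodes
  (isolated after thresholding) hidden;
* the **heterogeneous drug-ingredient-disease-target network** — one herb
  node, its active compounds, the disease node, and the drug/disease
  intersection genes, wired drug-ingredient, ingredient-target and
  disease-target.

Hub genes and key compounds are ranked by the three classic centralities as
reported by cytoHubba's undirected, un-normalized variants:

* ``DC`` — degree: raw neighbour count;
* ``CC`` — closeness: ``1 / sum of geodesic distances`` to every node
  reachable from v (the un-normalized reciprocal-total-distance form; the
  ``(n-1)/sum`` variant is available behind a flag);
* ``BC`` — betweenness: Brandes pair-dependency accumulation over unordered
  source-target pairs with endpoints excluded and fractional
  ``sigma_st(v)/sigma_st`` weighting.

Degree and the shortest-path centralities are computed by this module's own
BFS/Brandes implementations (the test suite cross-checks them against
exhaustive path enumeration and networkx); networkx supplies the graph
container and GraphML export.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .targetsets import TargetSet

__all__ = [
    "ScoredEdge",
    "HetNetwork",
    "NetworkSummary",
    "build_ppi",
    "load_scored_edges",
    "summarize",
    "format_avg_degree",
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "centrality_table",
    "rank_nodes",
    "build_didt_network",
    "compound_importance",
    "write_sif",
    "write_graphml",
]

logger = logging.getLogger(__name__)

NODE_TYPES = ("drug", "ingredient", "disease", "target")

#: canonical metric names with their cytoHubba-style aliases
_METRIC_ALIASES = {
    "degree": "degree", "dc": "degree",
    "closeness": "closeness", "cc": "closeness",
    "betweenness": "betweenness", "bc": "betweenness",
}


@dataclass(frozen=True)
class ScoredEdge:
    """One undirected interaction with a confidence score in [0, 1]."""

    node_a: str
    node_b: str
    score: float

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise ValueError(f"self-loop on {self.node_a!r} is not a valid interaction")
        if not (0 <= self.score <= 1):
            raise ValueError(
                f"score must be in [0, 1], got {self.score} for "
                f"({self.node_a}, {self.node_b})"
            )


class HetNetwork:
    """Simple undirected graph with typed nodes and optionally scored edges.

    Invariants enforced at construction time: no self-loops, no parallel
    edges (duplicates collapse keeping the maximum score), and every edge
    endpoint is a declared node.  Backed by a :class:`networkx.Graph`
    (available as ``.graph``) so standard graph algorithms and exporters
    apply directly.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()

    # -- construction -----------------------------------------------------

    def add_node(self, node_id: str, node_type: str = "target") -> None:
        if node_type not in NODE_TYPES:
            raise ValueError(f"unknown node_type {node_type!r}; expected one of {NODE_TYPES}")
        if node_id in self.graph and self.graph.nodes[node_id]["node_type"] != node_type:
            raise ValueError(
                f"node {node_id!r} already declared with type "
                f"{self.graph.nodes[node_id]['node_type']!r}"
            )
        self.graph.add_node(node_id, node_type=node_type)

    def add_edge(self, a: str, b: str, score: float | None = None) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a!r} rejected")
        for endpoint in (a, b):
            if endpoint not in self.graph:
                raise ValueError(f"edge endpoint {endpoint!r} is not a declared node")
        if score is not None and not (0 <= score <= 1):
            raise ValueError(f"edge score must be in [0, 1], got {score}")
        if self.graph.has_edge(a, b):
            old = self.graph.edges[a, b].get("score")
            if score is not None and (old is None or score > old):
                self.graph.edges[a, b]["score"] = score
            return
        if score is None:
            self.graph.add_edge(a, b)
        else:
            self.graph.add_edge(a, b, score=score)

    # -- inspection -------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    def node_type(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["node_type"]

    def nodes_of_type(self, node_type: str) -> list[str]:
        return [n for n, t in self.graph.nodes(data="node_type") if t == node_type]

    def adjacency(self) -> dict[str, list[str]]:
        return {n: list(self.graph.neighbors(n)) for n in self.graph.nodes}


@dataclass(frozen=True)
class NetworkSummary:
    """Node/edge counts and the mean degree ``2E/N`` (full precision)."""

    n_nodes: int
    n_edges: int
    avg_degree: float


def load_scored_edges(path: str | Path) -> list[ScoredEdge]:
    """Read a scored edge list TSV.

    Accepts the native header ``node_a  node_b  score`` as well as the STRING
    export dialect ``protein1 protein2 combined_score`` (tab- or
    space-separated).  Scores on STRING's 0-1000 integer scale are detected
    (any value > 1) and divided by 1000.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=r"\s+", dtype=str)
    frame.columns = [c.strip().lower() for c in frame.columns]
    rename = {"protein1": "node_a", "protein2": "node_b", "combined_score": "score"}
    frame = frame.rename(columns=rename)
    missing = [c for c in ("node_a", "node_b", "score") if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing edge column(s): {', '.join(missing)}")
    scores = frame["score"].astype(float)
    if (scores > 1).any():
        scores = scores / 1000.0
    edges: list[ScoredEdge] = []
    for (a, b), s in zip(zip(frame["node_a"], frame["node_b"]), scores):
        a, b = a.strip(), b.strip()
        if a == b:
            logger.warning("%s: skipping self-loop on %r", path, a)
            continue
        edges.append(ScoredEdge(a, b, float(s)))
    return edges


def write_scored_edges(edges: Iterable[ScoredEdge], path: str | Path) -> None:
    """Write scored edges as TSV in the native ``node_a  node_b  score`` dialect."""
    lines = ["node_a\tnode_b\tscore"]
    lines += [f"{e.node_a}\t{e.node_b}\t{e.score}" for e in edges]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def build_ppi(
    edges: Iterable[ScoredEdge | tuple],
    threshold: float = 0.4,
    drop_isolated: bool = True,
    strict: bool = False,
) -> HetNetwork:
    """Build a PPI graph from scored edges, thresholding on confidence.

    Edges with ``score >= threshold`` survive (``>`` when ``strict=True``;
    STRING's "medium confidence 0.400" preset is the inclusive default).
    Duplicate edges collapse keeping the maximum score, input self-loops are
    skipped with a warning, and with ``drop_isolated`` nodes left without any
    surviving edge are hidden, mirroring the usual "hide free nodes" display
    choice.
    """
    if not (0 <= threshold <= 1):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    net = HetNetwork()
    all_nodes: set[str] = set()
    for edge in edges:
        if not isinstance(edge, ScoredEdge):
            a, b, s = edge
            if a == b:
                logger.warning("skipping self-loop on %r", a)
                continue
            edge = ScoredEdge(a, b, float(s))
        all_nodes.update((edge.node_a, edge.node_b))
        keep = edge.score > threshold if strict else edge.score >= threshold
        if not keep:
            continue
        for endpoint in (edge.node_a, edge.node_b):
            if endpoint not in net.graph:
                net.add_node(endpoint, "target")
        net.add_edge(edge.node_a, edge.node_b, edge.score)
    if not drop_isolated:
        for node in sorted(all_nodes - set(net.graph.nodes)):
            net.add_node(node, "target")
    return net


def summarize(net: HetNetwork) -> NetworkSummary:
    """Node count, edge count, and average degree ``2E/N`` at full precision."""
    if net.n_nodes == 0:
        raise ValueError("cannot summarize an empty graph")
    return NetworkSummary(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        avg_degree=2 * net.n_edges / net.n_nodes,
    )


def format_avg_degree(avg_degree: float, decimals: int = 1) -> str:
    """Render a mean degree truncated (not rounded) to ``decimals`` places.

    Truncation matches how interaction databases display mean degree:
    40 nodes / 233 edges give 11.65, displayed "11.6".
    """
    factor = 10 ** decimals
    truncated = math.floor(avg_degree * factor) / factor
    return f"{truncated:.{decimals}f}"


# ---------------------------------------------------------------------------
# centralities (own implementations; cross-checked against enumeration + nx)
# ---------------------------------------------------------------------------


def degree_centrality(net: HetNetwork) -> dict[str, int]:
    """Raw neighbour count per node (un-normalized DC)."""
    return {n: int(d) for n, d in net.graph.degree()}


def _bfs_distances(adj: Mapping[str, Sequence[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def closeness_centrality(net: HetNetwork, normalized: bool = False) -> dict[str, float]:
    """Closeness per node from unweighted BFS distances.

    Default is the un-normalized reciprocal form ``1 / sum_u d(v, u)`` with
    the sum restricted to v's connected component (so disconnected graphs
    produce finite values); ``normalized=True`` yields the usual
    ``(n_reachable - 1) / sum`` variant.  Nodes in singleton components get 0.
    """
    adj = net.adjacency()
    result: dict[str, float] = {}
    for v in adj:
        dist = _bfs_distances(adj, v)
        total = sum(dist.values())  # d(v, v) = 0 contributes nothing
        if total == 0:
            result[v] = 0.0
        elif normalized:
            result[v] = (len(dist) - 1) / total
        else:
            result[v] = 1.0 / total
    return result


def betweenness_centrality(net: HetNetwork) -> dict[str, float]:
    """Un-normalized Brandes betweenness over unordered pairs.

    ``BC(v) = sum over unordered pairs s != v != t of sigma_st(v)/sigma_st``
    where ``sigma_st`` counts shortest s-t paths.  Single-source dependency
    accumulation runs once per source; the ordered-pair total is halved at
    the end because the graph is undirected.  Leaves of a simple graph score
    exactly 0.
    """
    adj = net.adjacency()
    bc = {v: 0.0 for v in adj}
    for s in adj:
        # single-source shortest-path counting (BFS)
        stack: list[str] = []
        pred: dict[str, list[str]] = {v: [] for v in adj}
        sigma = {v: 0.0 for v in adj}
        dist = {v: -1 for v in adj}
        sigma[s] = 1.0
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        # dependency accumulation, endpoints excluded
        delta = {v: 0.0 for v in adj}
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return {v: x / 2.0 for v, x in bc.items()}


def centrality_table(net: HetNetwork, normalized_closeness: bool = False) -> pd.DataFrame:
    """DC/CC/BC per node with per-metric ranks (1 = most central).

    Ranks order descending by metric value, ties broken by ascending node id;
    the same rule :func:`rank_nodes` uses.
    """
    deg = degree_centrality(net)
    clo = closeness_centrality(net, normalized=normalized_closeness)
    bet = betweenness_centrality(net)
    nodes = sorted(net.graph.nodes)
    table = pd.DataFrame(
        {
            "node": nodes,
            "node_type": [net.node_type(n) for n in nodes],
            "degree": [deg[n] for n in nodes],
            "closeness": [clo[n] for n in nodes],
            "betweenness": [bet[n] for n in nodes],
        }
    )
    for metric, values in (("degree", deg), ("closeness", clo), ("betweenness", bet)):
        order = sorted(nodes, key=lambda n: (-values[n], n))
        rank = {n: i + 1 for i, n in enumerate(order)}
        table[f"rank_{metric}"] = [rank[n] for n in nodes]
    return table


def rank_nodes(table: pd.DataFrame, metric: str, top_k: int) -> list[str]:
    """Top-k node ids by a metric, descending, ties broken by ascending id."""
    key = _METRIC_ALIASES.get(metric.lower())
    if key is None:
        raise ValueError(f"unknown metric {metric!r}; expected DC/CC/BC or full names")
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    if top_k > len(table):
        logger.info("top_k=%d exceeds node count %d; returning all", top_k, len(table))
        top_k = len(table)
    ordered = table.sort_values([key, "node"], ascending=[False, True])
    return list(ordered["node"].head(top_k))


# ---------------------------------------------------------------------------
# heterogeneous drug-ingredient-disease-target graph
# ---------------------------------------------------------------------------


def build_didt_network(
    drug_id: str,
    ingredients: Sequence[str],
    ingredient_targets: Mapping[str, Iterable[str]],
    disease_id: str,
    disease_targets: TargetSet,
) -> HetNetwork:
    """Wire the drug-ingredient-disease-target graph.

    Edges: drug-ingredient for every ingredient, ingredient-target per the
    mapping, and disease-target for every target of ``disease_targets`` (the
    drug/disease intersection set).  Every mapped target must belong to
    ``disease_targets`` and every mapping key must be a declared ingredient.
    """
    if not ingredients:
        raise ValueError("at least one ingredient is required")
    unknown = set(ingredient_targets) - set(ingredients)
    if unknown:
        raise ValueError(
            f"ingredient_targets references undeclared ingredient(s): {sorted(unknown)}"
        )
    net = HetNetwork()
    net.add_node(drug_id, "drug")
    net.add_node(disease_id, "disease")
    for target in disease_targets.sorted_members():
        net.add_node(target, "target")
        net.add_edge(disease_id, target)
    for ingredient in ingredients:
        net.add_node(ingredient, "ingredient")
        net.add_edge(drug_id, ingredient)
    for ingredient, targets in ingredient_targets.items():
        for target in targets:
            if target not in disease_targets:
                raise ValueError(
                    f"mapped target {target!r} of {ingredient!r} is outside the "
                    f"disease target set {disease_targets.label!r}"
                )
            net.add_edge(ingredient, target)
    return net


def compound_importance(net: HetNetwork, normalized_closeness: bool = False) -> pd.DataFrame:
    """Centrality rows restricted to ingredient nodes, sorted by degree.

    Sorting is descending by degree with ties broken by ascending node id, so
    two compounds with identical connectivity order deterministically.
    """
    if not net.nodes_of_type("ingredient"):
        raise ValueError("network contains no ingredient-typed nodes")
    table = centrality_table(net, normalized_closeness=normalized_closeness)
    table = table[table["node_type"] == "ingredient"]
    table = table.sort_values(["degree", "node"], ascending=[False, True])
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# exporters (Cytoscape-loadable)
# ---------------------------------------------------------------------------


def write_sif(net: HetNetwork, path: str | Path, interaction: str = "pp") -> None:
    """Write edges as SIF (``nodeA TAB interaction TAB nodeB``); isolated
    nodes are emitted as bare single-column rows so they are not lost."""
    lines = [f"{a}\t{interaction}\t{b}" for a, b in sorted(net.edges())]
    lines += [n for n in sorted(net.nodes()) if net.graph.degree(n) == 0]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_graphml(net: HetNetwork, path: str | Path) -> None:
    """Write the graph as GraphML with ``node_type`` and ``score`` attributes."""
    nx.write_graphml(net.graph, path, encoding="utf-8")


def write_centrality_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")
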