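"""Network assembly from ranked edges, hub scoring and pruning.

The assembly rule mirrors how the ranked-edge list is turned into a usable
network: directed edges are added strictly in rank order until the
undirected projection forms a single connected component containing every
node; everything up to that rank is kept, redundant edges included.

Hubs are scored with the maximum-neighborhood-component statistics: MNC is
the node count of the largest connected component induced by a node's open
neighborhood, and DMNC is that component's edge count divided by its node
count raised to an exponent epsilon (1.7 by default).  Pruning then walks
edges in ascending weight order, removing any edge whose loss neither
disconnects the network nor strips an endpoint of its last link to a
top-quartile hub, until roughly ``target_ratio`` edges per node remain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .grn import RankedEdgeList

__all__ = [
    "Network",
    "HubScores",
    "assemble_single_component",
    "mnc",
    "dmnc",
    "hub_scores",
    "prune_network",
]


@dataclass
class Network:
    """Directed weighted network over a fixed node set.

    No self-loops, no duplicate directed edges.  The undirected projection
    (used by all connectivity and centrality computations) is available via
    :meth:`undirected`.
    """

    nodes: list[str]
    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        self.nodes = [str(n) for n in self.nodes]
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node ids")
        node_set = set(self.nodes)
        seen = set()
        for u, v, _ in self.edges:
            if u == v:
                raise ValueError(f"self-loop at {u!r}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge endpoint outside node set: {u}->{v}")
            if (u, v) in seen:
                raise ValueError(f"duplicate directed edge {u}->{v}")
            seen.add((u, v))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges)
        return g

    def undirected(self) -> nx.Graph:
        """Undirected projection; antiparallel edge pairs collapse to one."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for u, v, w in self.edges:
            if g.has_edge(u, v):
                g[u][v]["weight"] = max(g[u][v]["weight"], w)
            else:
                g.add_edge(u, v, weight=w)
        return g

    def is_single_component(self) -> bool:
        return nx.is_connected(self.undirected())

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.edges, columns=["source", "target", "weight"]).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )

    def write_sif(self, path) -> None:
        with open(path, "w") as fh:
            for u, v, _ in self.edges:
                fh.write(f"{u}\tregulates\t{v}\n")

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.digraph(), path)


@dataclass
class HubScores:
    """Per-node MNC / DMNC hub-importance scores."""

    mnc: dict[str, int]
    dmnc: dict[str, float]
    epsilon: float = 1.7

    def mean_rank(self) -> dict[str, float]:
        """Average of the two score ranks (1 = most hub-like)."""
        nodes = sorted(self.mnc)
        mnc_rank = _rank_desc([self.mnc[n] for n in nodes])
        dmnc_rank = _rank_desc([self.dmnc[n] for n in nodes])
        return {
            n: (mnc_rank[i] + dmnc_rank[i]) / 2.0 for i, n in enumerate(nodes)
        }

    def top_quartile(self) -> set[str]:
        ranks = self.mean_rank()
        nodes = sorted(ranks, key=lambda n: (ranks[n], n))
        k = max(1, math.ceil(len(nodes) / 4))
        return set(nodes[:k])


def _rank_desc(vals: list[float]) -> list[float]:
    """Average ranks, largest value -> rank 1."""
    order = sorted(range(len(vals)), key=lambda i: -vals[i])
    ranks = [0.0] * len(vals)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and vals[order[j + 1]] == vals[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def assemble_single_component(
    ranked: RankedEdgeList, node_set: list[str]
) -> tuple[Network, int]:
    """Add ranked edges until one component spans the whole node set.

    Returns the assembled network and ``edges_used``, the number of ranked
    edges consumed when full (weak) connectivity is first reached.  All
    edges up to that rank are retained, including redundant ones.  Raises
    ``ValueError`` (reporting the residual components) if the list runs out
    first.
    """
    nodes = [str(n) for n in node_set]
    want = set(nodes)
    parent: dict[str, str] = {n: n for n in nodes}
    size: dict[str, int] = {n: 1 for n in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    n_components = len(nodes)
    edges: list[tuple[str, str, float]] = []
    for rank, (u, v, w) in enumerate(ranked, start=1):
        if u not in want or v not in want:
            continue
        edges.append((u, v, w))
        ru, rv = find(u), find(v)
        if ru != rv:
            if size[ru] < size[rv]:
                ru, rv = rv, ru
            parent[rv] = ru
            size[ru] += size[rv]
            n_components -= 1
            if n_components == 1:
                return Network(nodes=nodes, edges=edges), rank
    comps: dict[str, list[str]] = {}
    for n in nodes:
        comps.setdefault(find(n), []).append(n)
    sizes = sorted((len(c) for c in comps.values()), reverse=True)
    raise ValueError(
        f"ranked list exhausted with {len(comps)} components (sizes {sizes[:10]})"
    )


def _mnc_component(g: nx.Graph, node: str) -> nx.Graph:
    """Largest connected component of the open-neighborhood subgraph."""
    if node not in g:
        raise KeyError(f"unknown node {node!r}")
    nbrs = set(g[node])
    if not nbrs:
        return nx.Graph()
    sub = g.subgraph(nbrs)
    best = max(
        nx.connected_components(sub),
        key=lambda c: (len(c), sub.subgraph(c).number_of_edges(), sorted(c)),
    )
    return sub.subgraph(best).copy()


def mnc(net: Network, node: str) -> int:
    """Maximum neighborhood component: node count of the largest connected
    component induced by the node's neighbors (undirected projection)."""
    comp = _mnc_component(net.undirected(), node)
    return comp.number_of_nodes()


def dmnc(net: Network, node: str, epsilon: float = 1.7) -> float:
    """Density of the maximum neighborhood component: |E| / |V|**epsilon,
    0 when the component has fewer than 2 nodes."""
    comp = _mnc_component(net.undirected(), node)
    n = comp.number_of_nodes()
    if n < 2:
        return 0.0
    return comp.number_of_edges() / n**epsilon


def hub_scores(net: Network, epsilon: float = 1.7) -> HubScores:
    """MNC and DMNC for every node, computed on one shared projection."""
    g = net.undirected()
    mnc_d: dict[str, int] = {}
    dmnc_d: dict[str, float] = {}
    for node in net.nodes:
        comp = _mnc_component(g, node)
        n = comp.number_of_nodes()
        mnc_d[node] = n
        dmnc_d[node] = comp.number_of_edges() / n**epsilon if n >= 2 else 0.0
    return HubScores(mnc=mnc_d, dmnc=dmnc_d, epsilon=epsilon)


def prune_network(
    net: Network, hub: HubScores | None = None, target_ratio: float = 5.0
) -> Network:
    """Remove weak edges down to about ``target_ratio`` edges per node.

    Directed edges are visited in ascending weight order (ties broken
    lexicographically).  An edge is kept if removing it would disconnect
    the undirected projection, or if it is either endpoint's last remaining
    link to a top-quartile hub (hubs ranked by the mean of their MNC and
    DMNC ranks).  Stops once the directed edge count drops to
    ``ceil(target_ratio * n_nodes)`` or no edge is removable.  The result
    is always a single component over the full node set.
    """
    if not net.is_single_component():
        raise ValueError("input network is not a single connected component")
    if hub is None:
        hub = hub_scores(net)
    hubs = hub.top_quartile()
    target = math.ceil(target_ratio * net.n_nodes)

    edges = set((u, v) for u, v, _ in net.edges)
    weight = {(u, v): w for u, v, w in net.edges}
    # multiplicity of each undirected link (1 or 2 for antiparallel pairs)
    proj_mult: dict[frozenset, int] = {}
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for u, v, _ in net.edges:
        key = frozenset((u, v))
        proj_mult[key] = proj_mult.get(key, 0) + 1
        g.add_edge(u, v)
    # per-node count of undirected neighbors that are hubs
    hub_links = {n: sum(1 for nb in g[n] if nb in hubs) for n in g}

    order = sorted(edges, key=lambda e: (weight[e], e[0], e[1]))
    n_edges = len(edges)
    for u, v in order:
        if n_edges <= target:
            break
        if (u, v) not in edges:
            continue
        key = frozenset((u, v))
        last_projection = proj_mult[key] == 1
        if last_projection:
            # protect hub lifelines
            if (v in hubs and hub_links[u] == 1) or (u in hubs and hub_links[v] == 1):
                continue
            # protect bridges
            g.remove_edge(u, v)
            if not nx.has_path(g, u, v):
                g.add_edge(u, v)
                continue
            proj_mult[key] = 0
            if v in hubs:
                hub_links[u] -= 1
            if u in hubs:
                hub_links[v] -= 1
        else:
            proj_mult[key] -= 1
        edges.discard((u, v))
        n_edges -= 1

    kept = sorted(edges)
    return Network(
        nodes=list(net.nodes), edges=[(u, v, weight[(u, v)]) for u, v in kept]
    )
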