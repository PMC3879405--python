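import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from baculonet.expression import ExpressionSeries
from baculonet.netbuild import Network


def make_series(values, times=None, reps=None, genes=None, **kwargs):
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if genes is None:
        genes = [f"g{i + 1}" for i in range(n_genes)]
    if times is None:
        times = np.arange(n_samples, dtype=float)
    if reps is None:
        reps = np.ones(n_samples, dtype=int)
    return ExpressionSeries(
        gene_ids=genes,
        sample_times=np.asarray(times, dtype=float),
        replicate_of=np.asarray(reps, dtype=int),
        values=values,
        **kwargs,
    )


def net_from_edges(edges, nodes=None):
    if nodes is None:
        nodes = sorted({n for e in edges for n in e[:2]})
    return Network(
        nodes=list(nodes),
        edges=[(e[0], e[1], e[2] if len(e) > 2 else 1.0) for e in edges],
    )


def random_connected_graph(rng, n, p=0.4):
    """Random undirected connected graph as an adjacency dict."""
    import networkx as nx

    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_nodes() >= 2 and nx.is_connected(g):
            return g


def graph_to_network(g):
    """Undirected networkx graph -> directed Network (one direction per edge)."""
    nodes = [str(n) for n in sorted(g.nodes())]
    edges = [(str(u), str(v), 1.0) for u, v in sorted(map(sorted, g.edges()))]
    return Network(nodes=nodes, edges=edges)


def adjacency_dict(g):
    return {str(n): [str(v) for v in g[n]] for n in g.nodes()}


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
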