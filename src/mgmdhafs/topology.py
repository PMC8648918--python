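"""Graph-topology features for proteins from an interaction edge list.

The interactome is an undirected simple graph; per-node centrality measures
are emitted as named columns joinable to a feature table by node id.  The
registry covers the main named measures (degree, Brandes betweenness,
closeness, ...) plus common Cytoscape-NetworkAnalyzer-style parameters;
additional measures can be plugged in through :data:`MEASURES`.

Disconnected graphs follow the NetworkAnalyzer convention: closeness,
eccentricity, mean shortest path and radiality are computed within the node's
connected component; isolated nodes get 0.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def read_edge_list(path) -> nx.Graph:
    """Read a two-column TSV (``A<TAB>B``) or SIF (``A<TAB>type<TAB>B``) edge
    list into a deduplicated undirected simple graph; self-loops are dropped
    with a logged count."""
    graph = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) == 2:
                a, b = fields
            elif len(fields) >= 3:  # SIF: source, interaction type, target(s)
                a, b = fields[0], fields[2]
            else:
                raise ValueError(f"malformed edge line {lineno}: {line!r}")
            if not a or not b:
                raise ValueError(f"malformed edge line {lineno}: {line!r}")
            if a == b:
                n_self += 1
                graph.add_node(a)
                continue
            graph.add_edge(a, b)
    if n_self:
        logger.info("dropped %d self-loop(s)", n_self)
    return graph


# -- individual measures -----------------------------------------------------

def _per_component(graph, func):
    out = {}
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        out.update(func(sub))
    return out


def _degree(g):
    return dict(g.degree())


def _betweenness(g):
    return nx.betweenness_centrality(g, normalized=False)


def _betweenness_normalized(g):
    return nx.betweenness_centrality(g, normalized=True)


def _closeness(g):
    # within-component: (n_c - 1) / sum of distances
    return nx.closeness_centrality(g, wf_improved=False)


def _clustering(g):
    return nx.clustering(g)


def _eccentricity(g):
    return _per_component(g, lambda s: nx.eccentricity(s) if s.number_of_nodes() > 1
                          else {next(iter(s)): 0})


def _mean_shortest_path(g):
    def comp(sub):
        n = sub.number_of_nodes()
        if n == 1:
            return {next(iter(sub)): 0.0}
        return {v: sum(d.values()) / (n - 1)
                for v, d in nx.shortest_path_length(sub)}
    return _per_component(g, comp)


def _eigenvector(g):
    def comp(sub):
        if sub.number_of_nodes() == 1:
            return {next(iter(sub)): 0.0}
        if sub.number_of_edges() == 0:
            return {v: 0.0 for v in sub}
        return nx.eigenvector_centrality(sub, max_iter=1000, tol=1e-10)
    return _per_component(g, comp)


def _neighborhood_connectivity(g):
    out = {}
    for v in g:
        nbrs = list(g[v])
        out[v] = float(np.mean([g.degree(u) for u in nbrs])) if nbrs else 0.0
    return out


def _stress(g):
    """Stress centrality: the number of shortest paths passing through a node
    (Brandes-style accumulation per source, halved for undirected pairs)."""
    stress = dict.fromkeys(g, 0.0)
    for s in g:
        # BFS with shortest-path counting
        sigma = dict.fromkeys(g, 0.0)
        sigma[s] = 1.0
        dist = {s: 0}
        preds = {v: [] for v in g}
        stack = []
        queue = [s]
        head = 0
        while head < len(queue):
            v = queue[head]; head += 1
            stack.append(v)
            for w in g[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        # delta[v] = number of shortest-path continuations from v to any target
        delta = dict.fromkeys(g, 0.0)
        for w in reversed(stack):
            for v in preds[w]:
                delta[v] += (sigma[v] / sigma[w]) * (sigma[w] + delta[w])
            if w != s:
                stress[w] += delta[w]
    return {v: val / 2.0 for v, val in stress.items()}


def _radiality(g):
    def comp(sub):
        n = sub.number_of_nodes()
        if n == 1:
            return {next(iter(sub)): 0.0}
        sp = dict(nx.shortest_path_length(sub))
        diameter = max(max(d.values()) for d in sp.values())
        return {v: sum(diameter + 1 - d for u, d in sp[v].items() if u != v) / (n - 1)
                for v in sub}
    return _per_component(g, comp)


def _topological_coefficient(g):
    """Cytoscape definition: for node n with k_n >= 2 neighbors,
    TC_n = mean_m J(n, m) / k_n over all nodes m sharing >= 1 neighbor with n,
    where J(n, m) = #shared neighbors (+1 if m is itself a neighbor of n)."""
    out = {}
    for n in g:
        nbrs = set(g[n])
        if len(nbrs) < 2:
            out[n] = 0.0
            continue
        j_values = []
        for m in g:
            if m == n:
                continue
            shared = len(nbrs & set(g[m]))
            if shared == 0:
                continue
            j_values.append(shared + (1 if m in nbrs else 0))
        out[n] = float(np.mean(j_values) / len(nbrs)) if j_values else 0.0
    return out


MEASURES = {
    "degree": _degree,
    "betweenness": _betweenness,
    "betweenness_normalized": _betweenness_normalized,
    "closeness": _closeness,
    "clustering": _clustering,
    "eccentricity": _eccentricity,
    "mean_shortest_path": _mean_shortest_path,
    "eigenvector": _eigenvector,
    "neighborhood_connectivity": _neighborhood_connectivity,
    "stress": _stress,
    "radiality": _radiality,
    "topological_coefficient": _topological_coefficient,
}


def compute_centralities(graph: nx.Graph, measures=("degree", "betweenness", "closeness")) -> pd.DataFrame:
    """Per-node topology feature columns (rows indexed by node id)."""
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    for m in measures:
        if m not in MEASURES:
            raise ValueError(f"unknown measure {m!r}; available: {sorted(MEASURES)}")
    nodes = list(graph.nodes())
    data = {m: MEASURES[m](graph) for m in measures}
    return pd.DataFrame({m: [data[m][v] for v in nodes] for m in measures},
                        index=nodes)
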