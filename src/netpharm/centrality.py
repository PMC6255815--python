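"""Node-centrality statistics for topological core-target screening.

Six statistics drive the two-stage screen, with the conventions of the
Cytoscape centrality tooling used in network-pharmacology practice:

- ``dc``  degree centrality, the raw degree |N(v)|;
- ``bc``  betweenness, the unnormalized shortest-path load
  sum over unordered pairs s != t != v of sigma_st(v)/sigma_st;
- ``cc``  closeness, r(v) / sum of distances to reachable nodes, where r(v)
  counts the nodes reachable from v (0 for isolated nodes);
- ``ec``  eigenvector centrality: the nonnegative principal eigenvector of
  the adjacency matrix, L2-normalized, computed on the largest connected
  component and 0 elsewhere (configurable to per-component);
- ``lac`` local average connectivity: the mean degree of v's neighbors
  within the subgraph induced on N(v);
- ``nc``  network centrality: the sum over incident edges of the edge
  clustering coefficient ECC(u,v) = z / min(deg(u)-1, deg(v)-1), z the
  number of common neighbors (0 when the denominator vanishes).

Subgraph centrality (``sc``) and information centrality (``ic``) are
optional extras, off by default.

Degree, betweenness and closeness delegate to networkx with the flags that
realise the conventions above; eigenvector centrality is a direct power
iteration (explicit tolerance and residual reporting); LAC and NC are
implemented here.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

DEFAULT_MEASURES = ("dc", "bc", "cc", "ec", "lac", "nc")
OPTIONAL_MEASURES = ("sc", "ic")


class ConvergenceError(RuntimeError):
    """Eigenvector power iteration failed to converge."""


def degree_centrality(net: nx.Graph) -> dict[str, float]:
    """dc(v) = |N(v)|, the raw degree."""
    return {n: float(d) for n, d in net.degree()}


def betweenness_centrality(net: nx.Graph) -> dict[str, float]:
    """Unnormalized betweenness over unordered node pairs, per component."""
    return nx.betweenness_centrality(net, normalized=False)


def closeness_centrality(net: nx.Graph) -> dict[str, float]:
    """cc(v) = (number reachable from v) / (sum of distances to them)."""
    return nx.closeness_centrality(net, wf_improved=False)


def eigenvector_centrality(
    net: nx.Graph,
    tol: float = 1e-10,
    max_iter: int = 1000,
    scope: str = "largest",
) -> dict[str, float]:
    """Nonnegative principal adjacency eigenvector, L2-normalized.

    Computed on the largest connected component (ties broken
    deterministically) with zeros elsewhere; ``scope="per-component"``
    normalizes within every component instead.  Components without edges
    score 0.  Raises :class:`ConvergenceError` with the residual if the
    power iteration does not converge within ``max_iter``.
    """
    if net.number_of_nodes() == 0:
        return {}
    out = {n: 0.0 for n in net.nodes}
    comps = sorted(nx.connected_components(net),
                   key=lambda c: (len(c), min(str(n) for n in c)))
    if scope == "largest":
        comps = [comps[-1]]
    elif scope != "per-component":
        raise ValueError(f"unknown scope: {scope!r}")
    for comp in comps:
        nodes = sorted(comp, key=str)
        sub = net.subgraph(nodes)
        if sub.number_of_edges() == 0:
            continue
        a = nx.to_numpy_array(sub, nodelist=nodes)
        x = np.full(len(nodes), 1.0 / np.sqrt(len(nodes)))
        residual = np.inf
        for _ in range(max_iter):
            # shifted iteration (A + I): same principal eigenvector, but a
            # guaranteed spectral gap so bipartite components cannot oscillate
            y = a @ x + x
            norm = np.linalg.norm(y)
            if norm == 0.0:
                break
            y /= norm
            residual = float(np.abs(y - x).max())
            x = y
            if residual < tol:
                break
        else:
            raise ConvergenceError(
                f"eigenvector power iteration: residual {residual:.3e} after {max_iter} iterations")
        x = np.abs(x)
        x /= np.linalg.norm(x)
        for n, v in zip(nodes, x):
            out[n] = float(v)
    return out


def local_average_connectivity(net: nx.Graph) -> dict[str, float]:
    """lac(v): average degree of v's neighbors inside the induced N(v) subgraph."""
    out = {}
    for v in net.nodes:
        nbrs = set(net.neighbors(v))
        if not nbrs:
            out[v] = 0.0
            continue
        # degree of w within G[N(v)] = |N(w) ∩ N(v)|
        total = sum(len(nbrs & set(net.neighbors(w))) for w in nbrs)
        out[v] = total / len(nbrs)
    return out


def edge_clustering_coefficient(
    net: nx.Graph, u, v, plus_one: bool = False
) -> float:
    """ECC(u,v) = z / min(deg(u)-1, deg(v)-1); 0 when the denominator is 0.

    ``plus_one`` switches to the (z+1)/min(...) variant.
    """
    du, dv = net.degree(u), net.degree(v)
    denom = min(du - 1, dv - 1)
    if denom <= 0:
        return 0.0
    z = len(set(net.neighbors(u)) & set(net.neighbors(v)))
    return ((z + 1) if plus_one else z) / denom


def network_centrality(net: nx.Graph, plus_one: bool = False) -> dict[str, float]:
    """nc(v): sum of edge clustering coefficients over v's incident edges."""
    return {
        v: sum(edge_clustering_coefficient(net, u, v, plus_one) for u in net.neighbors(v))
        for v in net.nodes
    }


def subgraph_centrality(net: nx.Graph) -> dict[str, float]:
    out = {n: 0.0 for n in net.nodes}
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        if sub.number_of_nodes() == 1:
            out[next(iter(comp))] = 1.0  # exp(A)=1 for a single node
            continue
        out.update(nx.subgraph_centrality(sub))
    return out


def information_centrality(net: nx.Graph) -> dict[str, float]:
    out = {n: 0.0 for n in net.nodes}
    for comp in nx.connected_components(net):
        if len(comp) < 2:
            continue
        out.update(nx.information_centrality(net.subgraph(comp)))
    return out


_DISPATCH = {
    "dc": degree_centrality,
    "bc": betweenness_centrality,
    "cc": closeness_centrality,
    "ec": eigenvector_centrality,
    "lac": local_average_connectivity,
    "nc": network_centrality,
    "sc": subgraph_centrality,
    "ic": information_centrality,
}


def compute_all(net: nx.Graph, measures=DEFAULT_MEASURES) -> pd.DataFrame:
    """Centrality table: one row per node, one column per requested measure.

    Deterministic (rows sorted by node identifier).  Unknown measure names
    raise ``ValueError``.
    """
    unknown = [m for m in measures if m not in _DISPATCH]
    if unknown:
        raise ValueError(f"unknown centrality measure(s): {', '.join(unknown)}")
    nodes = sorted(net.nodes, key=str)
    data = {m: _DISPATCH[m](net) for m in measures}
    return pd.DataFrame(
        {m: [data[m].get(n, 0.0) for n in nodes] for m in measures},
        index=pd.Index(nodes, name="node"),
    )
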