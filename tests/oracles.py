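"""Brute-force reference implementations, independent of the package's code
paths: explicit shortest-path enumeration, dense eigendecomposition, induced
subgraph counting, triangle enumeration, iterative k-core stripping, and
exhaustive hypergeometric subset enumeration."""

from itertools import combinations
from math import comb

import networkx as nx
import numpy as np


def _all_shortest_paths(g: nx.Graph, s, t):
    """Enumerate every shortest s-t path explicitly (BFS + backtracking)."""
    dist = {s: 0}
    order = [s]
    for u in order:
        for v in g.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                order.append(v)
    if t not in dist:
        return []
    paths = []

    def back(node, acc):
        if node == s:
            paths.append([s] + acc)
            return
        for w in g.neighbors(node):
            if dist.get(w, -2) == dist[node] - 1:
                back(w, [node] + acc)

    back(t, [])
    return paths


def bc_oracle(g: nx.Graph) -> dict:
    """Unnormalized betweenness by enumerating all shortest paths."""
    out = {v: 0.0 for v in g.nodes}
    for s, t in combinations(sorted(g.nodes), 2):
        paths = _all_shortest_paths(g, s, t)
        if not paths:
            continue
        for v in g.nodes:
            if v in (s, t):
                continue
            on_v = sum(1 for p in paths if v in p)
            out[v] += on_v / len(paths)
    return out


def cc_oracle(g: nx.Graph) -> dict:
    out = {}
    for v in g.nodes:
        dist = {v: 0}
        order = [v]
        for u in order:
            for w in g.neighbors(u):
                if w not in dist:
                    dist[w] = dist[u] + 1
                    order.append(w)
        total = sum(d for d in dist.values())
        out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def ec_oracle(g: nx.Graph) -> dict:
    """Dense eigendecomposition on the largest component, zeros elsewhere."""
    out = {v: 0.0 for v in g.nodes}
    comps = sorted(nx.connected_components(g),
                   key=lambda c: (len(c), min(str(n) for n in c)))
    if not comps:
        return out
    comp = comps[-1]
    nodes = sorted(comp, key=str)
    sub = g.subgraph(nodes)
    if sub.number_of_edges() == 0:
        return out
    a = nx.to_numpy_array(sub, nodelist=nodes)
    w, v = np.linalg.eigh(a)
    vec = np.abs(v[:, np.argmax(w)])
    vec = vec / np.linalg.norm(vec)
    for n, x in zip(nodes, vec):
        out[n] = float(x)
    return out


def lac_oracle(g: nx.Graph) -> dict:
    out = {}
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        if not nbrs:
            out[v] = 0.0
            continue
        sub = g.subgraph(nbrs)
        out[v] = sum(sub.degree(w) for w in nbrs) / len(nbrs)
    return out


def nc_oracle(g: nx.Graph) -> dict:
    """Summed edge clustering coefficients via explicit triangle counting."""
    out = {}
    for v in g.nodes:
        total = 0.0
        for u in g.neighbors(v):
            denom = min(g.degree(u) - 1, g.degree(v) - 1)
            if denom <= 0:
                continue
            z = sum(1 for w in g.nodes if g.has_edge(w, u) and g.has_edge(w, v))
            total += z / denom
        out[v] = total
    return out


def kcore_max_oracle(g: nx.Graph) -> tuple[int, set]:
    """(k, members) of the highest k-core by iterative stripping."""
    best_k, best = 0, set(g.nodes)
    k = 1
    nodes = set(g.nodes)
    while nodes:
        changed = True
        remaining = set(nodes)
        while changed:
            changed = False
            for v in list(remaining):
                if sum(1 for u in g.neighbors(v) if u in remaining) < k:
                    remaining.discard(v)
                    changed = True
        if not remaining:
            break
        best_k, best = k, remaining
        nodes = remaining
        k += 1
    return best_k, best


def hypergeom_tail_oracle(N: int, K: int, n: int, k: int) -> float:
    """P(|query ∩ term| >= k) by exhaustive enumeration of all n-subsets."""
    total = comb(N, n)
    hits = 0
    for subset in combinations(range(N), n):
        overlap = sum(1 for x in subset if x < K)
        if overlap >= k:
            hits += 1
    return hits / total
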