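"""MCODE dense-module detection.

Molecular Complex Detection finds locally dense regions of a PPI network in
three phases:

1. *Vertex weighting.*  Each node is scored by the density of the highest
   k-core of its closed neighborhood: weight(v) = k_max x density(k_max-core
   of G[N(v) U {v}]), with density = 2m/(n(n-1)).  Nodes below
   ``degree_cutoff`` get weight 0.
2. *Complex prediction.*  Starting from the highest-weighted unclustered
   node, a breadth-first expansion adds neighbors whose weight is at least
   seed_weight x (1 - VWP), up to ``max_depth`` hops; each node joins at
   most one cluster.
3. *Post-processing.*  Clusters lacking a ``k_core``-core are discarded;
   ``fluff`` optionally adds boundary neighbors whose closed-neighborhood
   density exceeds ``fluff_density`` (fluffed nodes may be shared between
   clusters); ``haircut`` then prunes singly-connected nodes until every
   member has at least two connections into the cluster.

Scores are density x size of the final member set; clusters are returned
score-descending with all ties broken by node-identifier order so the
procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx


@dataclass(frozen=True)
class McodeParams:
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2  # VWP: vertex weight percentage
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ValueError("node_score_cutoff (VWP) must be in [0, 1]")
        if self.k_core < 2:
            raise ValueError("k_core must be >= 2")


@dataclass(frozen=True)
class Cluster:
    members: frozenset
    seed: str
    score: float

    @property
    def size(self) -> int:
        return len(self.members)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def cluster_score(net: nx.Graph, members) -> float:
    """density x size of the induced member subgraph (the MCODE score)."""
    sub = net.subgraph(members)
    return _density(sub) * sub.number_of_nodes()


def vertex_weights(net: nx.Graph, params: McodeParams = McodeParams()) -> dict[str, float]:
    """Core-clustering-coefficient vertex weights."""
    weights = {}
    for v in net.nodes:
        if net.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        closed = set(net.neighbors(v)) | {v}
        sub = net.subgraph(closed)
        core_numbers = nx.core_number(sub)
        k_max = max(core_numbers.values())
        if k_max == 0:
            weights[v] = 0.0
            continue
        core_nodes = [n for n, k in core_numbers.items() if k >= k_max]
        weights[v] = k_max * _density(sub.subgraph(core_nodes))
    return weights


def _fluff(net: nx.Graph, members: set, params: McodeParams) -> set:
    extra = set()
    for v in members:
        for w in net.neighbors(v):
            if w in members or w in extra:
                continue
            closed = set(net.neighbors(w)) | {w}
            if _density(net.subgraph(closed)) > params.fluff_density:
                extra.add(w)
    return members | extra


def _haircut(net: nx.Graph, members: set) -> set:
    members = set(members)
    while True:
        sub = net.subgraph(members)
        trim = [v for v in members if sub.degree(v) < 2]
        if not trim or len(trim) == len(members):
            break
        members -= set(trim)
    return members


def find_clusters(
    net: nx.Graph,
    weights: dict[str, float] | None = None,
    params: McodeParams = McodeParams(),
) -> list[Cluster]:
    """Greedy seeded expansion into disjoint dense clusters, score-descending."""
    if weights is None:
        weights = vertex_weights(net, params)
    order = sorted(net.nodes, key=lambda n: (-weights[n], str(n)))
    clustered: set = set()
    clusters: list[Cluster] = []
    for seed in order:
        if seed in clustered or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        frontier = [seed]
        depth = 0
        seen = {seed}
        while frontier and depth < params.max_depth:
            nxt = []
            for u in frontier:
                for w in sorted(net.neighbors(u), key=str):
                    if w in seen or w in clustered:
                        continue
                    seen.add(w)
                    if weights[w] >= threshold:
                        members.add(w)
                        nxt.append(w)
            frontier = nxt
            depth += 1
        # require a k_core-core inside the raw cluster
        core = nx.k_core(net.subgraph(members), k=params.k_core)
        if core.number_of_nodes() == 0:
            continue
        clustered |= members
        if params.fluff:
            members = _fluff(net, members, params)
        if params.haircut:
            members = _haircut(net, members)
        if not members:
            continue
        if seed not in members:  # haircut/fluff may displace the origin node
            seed = min(members, key=lambda n: (-weights[n], str(n)))
        clusters.append(Cluster(frozenset(members), seed, cluster_score(net, members)))
    clusters.sort(key=lambda c: (-c.score, -c.size, str(c.seed)))
    return clusters


def write_clusters(clusters: list[Cluster], path) -> None:
    """TSV report: cluster_id, score, size, seed, comma-joined members."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tscore\tsize\tseed\tmembers\n")
        for i, c in enumerate(clusters, start=1):
            fh.write(f"C{i}\t{c.score:.6f}\t{c.size}\t{c.seed}\t"
                     f"{','.join(sorted(c.members))}\n")
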