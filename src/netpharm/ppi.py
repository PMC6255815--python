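"""Seed-expanded protein-protein interaction (PPI) networks.

A set of seed proteins (the formula's putative targets, or the disease's
known targets) is expanded against a user-supplied background interactome:
the expanded network contains every node within ``max_hops`` of a seed and,
by default, the full interactome subgraph induced on that node set
(neighbor-neighbor edges included) — the behaviour of seed-expansion tools
that grow a small seed list into a several-thousand-node network.  Two
expanded networks are then combined; the pipeline default is the
intersection (common nodes, common edges), which models the interactive
subnetwork shared by formula and disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .targets import TargetSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeedExpansionPolicy:
    include_neighbor_edges: bool = True
    max_hops: int = 1

    def __post_init__(self):
        if self.max_hops < 0:
            raise ValueError("max_hops must be >= 0")


def expand_seeds(
    interactome: nx.Graph,
    seeds: TargetSet,
    policy: SeedExpansionPolicy = SeedExpansionPolicy(),
) -> nx.Graph:
    """Grow a PPI network from seeds over the background interactome.

    Node set: seeds present in the interactome plus every interactome node
    within ``max_hops`` of one.  Edge set: the induced interactome subgraph
    when ``include_neighbor_edges``, else only seed-incident edges.  Seeds
    absent from the interactome are retained as isolated ``seed``-role nodes
    (count logged).
    """
    if interactome.number_of_nodes() == 0:
        logger.warning("expand_seeds: empty interactome; returning isolated seeds")
    present = {s for s in seeds.members if s in interactome}
    missing = sorted(seeds.members - present)
    frontier = set(present)
    reached = set(present)
    for _ in range(policy.max_hops):
        frontier = {v for u in frontier for v in interactome.neighbors(u)} - reached
        if not frontier:
            break
        reached |= frontier
    if policy.include_neighbor_edges:
        g = nx.Graph(interactome.subgraph(reached))
    else:
        g = nx.Graph()
        g.add_nodes_from(reached)
        g.add_edges_from(
            (u, v) for u in present for v in interactome.neighbors(u) if v in reached
        )
    for n in g.nodes:
        g.nodes[n]["role"] = "seed" if n in present else "interactor"
    for s in missing:
        g.add_node(s, role="seed")
    if missing:
        logger.info("expand_seeds: %d seed(s) absent from interactome kept isolated",
                    len(missing))
    logger.info("expand_seeds: %d seeds -> %d nodes, %d edges",
                len(seeds), g.number_of_nodes(), g.number_of_edges())
    return g


def intersect_networks(a: nx.Graph, b: nx.Graph, drop_isolated: bool = True) -> nx.Graph:
    """Common-node, common-edge intersection of two simple networks.

    Nodes left isolated by the edge intersection are removed when
    ``drop_isolated``.  Commutative, associative and idempotent.
    """
    g = nx.Graph()
    g.add_nodes_from(n for n in a.nodes if n in b)
    g.add_edges_from((u, v) for u, v in a.edges if b.has_edge(u, v))
    if drop_isolated:
        g.remove_nodes_from(list(nx.isolates(g)))
    for n in g.nodes:
        ra = a.nodes[n].get("role", "generic")
        rb = b.nodes[n].get("role", "generic")
        g.nodes[n]["role"] = ra if ra == rb else "generic"
    return g


def union_networks(a: nx.Graph, b: nx.Graph) -> nx.Graph:
    """Node/edge union of two simple networks (alternative merge semantics)."""
    g = nx.Graph()
    g.add_nodes_from(a.nodes(data=True))
    g.add_nodes_from(b.nodes(data=True))
    g.add_edges_from(a.edges)
    g.add_edges_from(b.edges)
    for n in g.nodes:
        g.nodes[n].setdefault("role", "generic")
    return g
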