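"""Graph and gene-list data model plus readers/writers.

The pipeline's universal currency is a simple undirected :class:`networkx.Graph`
whose nodes are non-empty string identifiers carrying a ``role`` attribute
(``component``, ``target``, ``interactor``, ``seed`` or ``generic``). All
constructors in this module enforce simplicity: self-loops are dropped (with a
logged count) and duplicate edges collapse, since every downstream statistic
(centralities, MCODE) assumes a simple graph.

Gene symbols are normalized to uppercase with surrounding whitespace stripped;
generic interactome identifiers are kept case-sensitive.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)

ROLES = ("component", "target", "interactor", "seed", "generic")


class ParseError(ValueError):
    """Raised for malformed rows in any of the text formats."""


def normalize_symbol(value: str) -> str:
    """Normalize a gene symbol: strip surrounding whitespace, uppercase.

    Idempotent: ``normalize_symbol(normalize_symbol(x)) == normalize_symbol(x)``.
    """
    return value.strip().upper()


def new_network(edges: Iterable[tuple[str, str]] = (), role: str = "generic") -> nx.Graph:
    """Build a simple undirected network from an edge iterable.

    Self-loops are silently dropped (count logged); duplicate edges collapse.
    """
    g = nx.Graph()
    dropped = 0
    for u, v in edges:
        if u == v:
            dropped += 1
            continue
        g.add_edge(u, v)
    if dropped:
        logger.info("dropped %d self-loop(s)", dropped)
    nx.set_node_attributes(g, role, "role")
    return g


def canonical_edges(net: nx.Graph) -> list[tuple[str, str]]:
    """Edges under the canonical (lexicographic-pair, then sorted) ordering."""
    return sorted(tuple(sorted((str(u), str(v)))) for u, v in net.edges())


def read_edge_list(path: str | Path, format: str = "tsv") -> nx.Graph:
    """Read an undirected edge list from TSV or SIF into a simple network.

    TSV rows need at least two tab-separated node fields; ``#``-prefixed
    comment lines and blank lines are ignored.  A SIF row
    ``nodeA <relation> nodeB [nodeC ...]`` fans out to edges A-B, A-C, ...
    Self-loops and duplicate rows are collapsed; dropped counts are logged.
    """
    path = Path(path)
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format: {format!r}")
    g = nx.Graph()
    dropped_loops = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if format == "sif" and len(fields) == 1:
                fields = line.split()
            if format == "tsv":
                if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                    raise ParseError(f"{path}:{lineno}: expected >=2 node fields")
                pairs = [(fields[0].strip(), fields[1].strip())]
            else:  # sif: nodeA relation nodeB [nodeC ...]; single-node rows allowed
                src = fields[0].strip()
                if not src:
                    raise ParseError(f"{path}:{lineno}: empty source node")
                if len(fields) == 1:
                    g.add_node(src)
                    continue
                if len(fields) < 3:
                    raise ParseError(f"{path}:{lineno}: SIF row needs relation and >=1 target")
                pairs = [(src, t.strip()) for t in fields[2:] if t.strip()]
            for u, v in pairs:
                if u == v:
                    dropped_loops += 1
                    continue
                g.add_edge(u, v)
    if dropped_loops:
        logger.info("%s: dropped %d self-loop record(s)", path.name, dropped_loops)
    for n in g.nodes:
        g.nodes[n].setdefault("role", "generic")
    return g


def write_network(net: nx.Graph, path: str | Path, format: str = "tsv") -> None:
    """Write a network as TSV/SIF edge list or GraphML (role tags preserved)."""
    path = Path(path)
    if format == "graphml":
        g = net.copy()
        for n in g.nodes:
            g.nodes[n].setdefault("role", "generic")
        nx.write_graphml(g, path)
        return
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown network format: {format!r}")
    with path.open("w") as fh:
        if format == "tsv":
            for u, v in canonical_edges(net):
                fh.write(f"{u}\t{v}\n")
            for n in sorted(nx.isolates(net)):
                # isolated nodes have no TSV representation; note them as comments
                fh.write(f"# isolated\t{n}\n")
        else:
            for u, v in canonical_edges(net):
                fh.write(f"{u}\tpp\t{v}\n")
            for n in sorted(nx.isolates(net)):
                fh.write(f"{n}\n")


def read_graphml(path: str | Path) -> nx.Graph:
    g = nx.read_graphml(Path(path))
    g = nx.Graph(g)
    g.remove_edges_from(nx.selfloop_edges(g))
    for n in g.nodes:
        g.nodes[n].setdefault("role", "generic")
    return g


def read_gene_list(path: str | Path) -> list[str]:
    """Read one normalized gene symbol per line (single-column TSV).

    Order-preserving; duplicates retained (dedup is the target-set layer's
    job).  An optional ``#`` header line is skipped; an empty file yields an
    empty list.
    """
    out: list[str] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            out.append(normalize_symbol(line.split("\t")[0]))
    return out


def write_gene_list(symbols: Iterable[str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for s in symbols:
            fh.write(f"{s}\n")


def apply_mapping(symbols: Iterable[str], mapping: dict[str, str]) -> list[str]:
    """Apply a user-supplied identifier mapping as a plain join; unmapped
    symbols pass through unchanged."""
    return [mapping.get(s, s) for s in symbols]
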