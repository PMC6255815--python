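"""Target-set algebra and the component-target bipartite network.

Formula-side targets (predicted for bioactive components) and disease-side
targets (collected from several gene-disease databases) are represented as
labelled sets of normalized gene symbols.  The module intersects them into
the "common target" set and builds the component-target bipartite network
whose component-node degrees rank candidate components.
"""

from __future__ import annotations

import csv
import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .graphio import ParseError, normalize_symbol

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetSet:
    """A labelled, deduplicated set of normalized gene symbols."""

    label: str
    members: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def from_symbols(cls, label: str, symbols) -> "TargetSet":
        return cls(label, frozenset(normalize_symbol(s) for s in symbols if s.strip()))

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ComponentTargetTable:
    """Distinct (component_id, gene symbol) pairs after normalization."""

    pairs: tuple[tuple[str, str], ...]

    @classmethod
    def from_pairs(cls, pairs) -> "ComponentTargetTable":
        seen = set()
        out = []
        for cid, sym in pairs:
            cid = str(cid).strip()
            sym = normalize_symbol(str(sym))
            if not cid or not sym:
                raise ParseError("component-target pair with empty field")
            if (cid, sym) not in seen:
                seen.add((cid, sym))
                out.append((cid, sym))
        return cls(tuple(out))

    def target_set(self, label: str = "formula") -> TargetSet:
        return TargetSet(label, frozenset(sym for _, sym in self.pairs))

    def components(self) -> list[str]:
        seen: dict[str, None] = {}
        for cid, _ in self.pairs:
            seen.setdefault(cid)
        return list(seen)


def read_pair_table(path: str | Path) -> ComponentTargetTable:
    """Read a 2-column TSV of (component_id, target symbol) pairs.

    A non-data first row (header) is skipped; ``#`` comments ignored.
    """
    path = Path(path)
    pairs = []
    with path.open() as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if len(row) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and row[0].strip().lower() in ("component_id", "component"):
                continue
            pairs.append((row[0], row[1]))
    return ComponentTargetTable.from_pairs(pairs)


def write_pair_table(table: ComponentTargetTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("component_id\ttarget\n")
        for cid, sym in table.pairs:
            fh.write(f"{cid}\t{sym}\n")


def union_targets(lists: list[TargetSet], label: str = "union") -> TargetSet:
    """Set union of several target lists (duplicate removal across sources)."""
    if not lists:
        raise ValueError("union_targets needs at least one TargetSet")
    members: frozenset[str] = frozenset()
    for ts in lists:
        members |= ts.members
    return TargetSet(label, members)


def intersect_targets(a: TargetSet, b: TargetSet, label: str = "common") -> TargetSet:
    """Members present in both sets — the formula/disease common targets."""
    return TargetSet(label, a.members & b.members)


def build_bipartite(table: ComponentTargetTable) -> nx.Graph:
    """Component-target bipartite network: one node per distinct component
    (role ``component``) and per distinct target (role ``target``), one edge
    per distinct pair."""
    g = nx.Graph()
    for cid, sym in table.pairs:
        g.add_node(cid, role="component")
        g.add_node(sym, role="target")
        g.add_edge(cid, sym)
    return g


def candidate_components(
    net: nx.Graph, min_degree: int | str = "median"
) -> list[tuple[str, int]]:
    """Component nodes with degree >= threshold, degree-descending.

    ``min_degree="median"`` uses the interpolated median of the
    component-node degrees (target nodes excluded).  Ties broken by node id.
    """
    comp_nodes = [n for n, d in net.nodes(data=True) if d.get("role") == "component"]
    if not comp_nodes:
        logger.warning("candidate_components: no component-role nodes in network")
        return []
    degrees = {n: net.degree(n) for n in comp_nodes}
    if min_degree == "median":
        threshold: float = statistics.median(degrees.values())
    else:
        threshold = float(min_degree)
    logger.info("candidate_components: degree threshold %.3f", threshold)
    kept = [(n, d) for n, d in degrees.items() if d >= threshold]
    return sorted(kept, key=lambda t: (-t[1], t[0]))
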