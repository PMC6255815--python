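"""Two-stage topological core-target screen.

Stage 1 keeps every node whose degree is at least ``multiplier`` times the
interpolated median degree (default multiplier 2) and induces the subgraph
on those nodes.  Stage 2 recomputes all six centrality statistics *on the
stage-1 subnetwork* and keeps the nodes that strictly exceed all six
cutoffs simultaneously; by default each cutoff is that measure's
interpolated median over the stage-1 subnetwork, and an explicit-cutoff
mode accepts externally chosen values.  Recomputing on the reduced network
matters: a stage-2 degree cutoff can legitimately exceed the stage-1 entry
cutoff because medians shift upward on the dense core.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .centrality import DEFAULT_MEASURES, compute_all

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    stage1_threshold: float
    stage1_network: nx.Graph
    stage2_thresholds: dict[str, float]
    core_nodes: set = field(default_factory=set)
    core_network: nx.Graph = field(default_factory=nx.Graph)


def stage1_filter(
    net: nx.Graph,
    table: pd.DataFrame | None = None,
    multiplier: float = 2.0,
    strict: bool = False,
) -> tuple[nx.Graph, float]:
    """Induced subgraph on nodes with dc >= multiplier x median(dc).

    The median is interpolated over all nodes of ``net``.  Returns the
    subgraph and the threshold actually applied (logged).  ``strict``
    switches the comparison to >.
    """
    if net.number_of_nodes() == 0:
        logger.warning("stage1_filter: empty network")
        return nx.Graph(), 0.0
    if table is None or "dc" not in table:
        degrees = {n: float(d) for n, d in net.degree()}
    else:
        degrees = table["dc"].to_dict()
    threshold = multiplier * statistics.median(degrees[n] for n in net.nodes)
    logger.info("stage1_filter: dc threshold %.3f (multiplier %.2f)", threshold, multiplier)
    if strict:
        keep = [n for n in net.nodes if degrees[n] > threshold]
    else:
        keep = [n for n in net.nodes if degrees[n] >= threshold]
    return nx.Graph(net.subgraph(keep)), threshold


def stage2_thresholds(
    sub: nx.Graph,
    rule: str = "median",
    explicit: dict[str, float] | None = None,
    measures=DEFAULT_MEASURES,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Per-measure cutoffs for the second screening stage.

    ``rule="median"`` recomputes every measure on the stage-1 subnetwork and
    takes its interpolated median; ``rule="explicit"`` uses user-supplied
    cutoffs (all measures required).  Returns (cutoffs, centrality table on
    ``sub``).
    """
    table = compute_all(sub, measures)
    if rule == "median":
        if sub.number_of_nodes() == 0:
            raise ValueError("stage2_thresholds: empty stage-1 subnetwork")
        cutoffs = {m: float(statistics.median(table[m])) for m in measures}
    elif rule == "explicit":
        if explicit is None:
            raise ValueError("explicit rule requires cutoffs")
        missing = [m for m in measures if m not in explicit]
        if missing:
            raise ValueError(f"explicit cutoffs missing measure(s): {', '.join(missing)}")
        cutoffs = {m: float(explicit[m]) for m in measures}
    else:
        raise ValueError(f"unknown stage-2 rule: {rule!r}")
    for m in measures:
        logger.info("stage2 cutoff %s > %.6g", m, cutoffs[m])
    return cutoffs, table


def stage2_filter(
    sub: nx.Graph,
    cutoffs: dict[str, float],
    table: pd.DataFrame | None = None,
    strict: bool = True,
) -> tuple[set, nx.Graph]:
    """Core nodes: those exceeding every cutoff simultaneously (strict >).

    Returns the core node set and the induced core network.
    """
    if table is None:
        table = compute_all(sub, tuple(cutoffs))
    missing = [m for m in cutoffs if m not in table.columns]
    if missing:
        raise ValueError(f"centrality table lacks measure(s): {', '.join(missing)}")
    mask = pd.Series(True, index=table.index)
    for m, cut in cutoffs.items():
        mask &= (table[m] > cut) if strict else (table[m] >= cut)
    core = set(table.index[mask])
    return core, nx.Graph(sub.subgraph(core))


def run_screen(
    net: nx.Graph,
    multiplier: float = 2.0,
    rule: str = "median",
    explicit: dict[str, float] | None = None,
    measures=DEFAULT_MEASURES,
) -> ScreenResult:
    """Full two-stage screen on a network; deterministic."""
    sub, threshold = stage1_filter(net, multiplier=multiplier)
    if sub.number_of_nodes() == 0:
        logger.warning("run_screen: stage-1 subnetwork empty; core is empty")
        return ScreenResult(threshold, sub, {}, set(), nx.Graph())
    cutoffs, table = stage2_thresholds(sub, rule=rule, explicit=explicit, measures=measures)
    core, core_net = stage2_filter(sub, cutoffs, table)
    logger.info("run_screen: %d node(s) -> stage1 %d -> core %d",
                net.number_of_nodes(), sub.number_of_nodes(), len(core))
    return ScreenResult(threshold, sub, cutoffs, core, core_net)
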