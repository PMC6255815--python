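"""Synthetic inputs with known ground truth for every pipeline stage.

Real runs of this pipeline consume frozen database exports (component ADME
tables, ligand-target predictions, disease-gene lists, a merged
interactome).  The generators here emulate each input's statistical shape —
controllable ADME pass rates, heavy-tailed component degrees, a controlled
formula/disease overlap, a preferential-attachment interactome with planted
dense modules and planted hubs, and a GMT collection with one spiked term —
and record the planted truth so each consumer's output is predictable.

Every generator is a pure function of its parameters and a seed; a single
pipeline-wide seed fans out to per-generator derived seeds so one integer
reproduces an entire fixture byte-for-byte.

:func:`paper_shaped` bundles the generators into the default study-shaped
fixture: 600 components across four herbs with a 22 % ADME pass rate plus
nine curation-flagged keeps, 186 predicted targets spread over 118
bioactive components with mean degree ~21, 546 disease targets sharing 52
with the formula side, and a 1500-node interactome (attachment m=3,
triangle start) carrying one degree-300 hub inside a 40-node dense module
plus two smaller planted modules.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .adme import ComponentRecord, write_component_table
from .enrich import AnnotationCollection, write_gmt
from .graphio import write_network, write_gene_list
from .targets import ComponentTargetTable, TargetSet, write_pair_table

_STAGE = {"components": 1, "pairs": 2, "disease": 3, "interactome": 4, "annotations": 5}


def derive_seed(seed: int, stage: str) -> int:
    """Per-stage child seed (< 2**31) from the pipeline-wide seed."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE[stage],))
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


@dataclass
class SyntheticTruth:
    """Planted ground truth of a generated fixture."""

    seed: int
    params: dict = field(default_factory=dict)
    expected_pass_components: set = field(default_factory=set)
    expected_retained_components: set = field(default_factory=set)
    component_degrees: dict = field(default_factory=dict)
    formula_targets: set = field(default_factory=set)
    disease_targets: set = field(default_factory=set)
    expected_common: set = field(default_factory=set)
    planted_modules: list = field(default_factory=list)  # (members, p_intra)
    planted_hubs: set = field(default_factory=set)
    spiked_term: str | None = None

    def to_json(self, path: str | Path) -> None:
        def _conv(x):
            if isinstance(x, (set, frozenset)):
                return sorted(x)
            if isinstance(x, tuple):
                return list(x)
            raise TypeError(type(x))
        with Path(path).open("w") as fh:
            json.dump(dataclasses.asdict(self), fh, default=_conv,
                      indent=1, sort_keys=True)


def gen_components(
    n_per_herb: dict[str, int],
    pass_fraction: float,
    seed: int,
    n_manual_keep: int = 0,
    missing_fraction: float = 0.05,
) -> tuple[list[ComponentRecord], SyntheticTruth]:
    """Component ADME table with a controlled pass rate.

    A ``pass_fraction`` share of records draws OB ~ U(20, 60) and
    DL ~ U(0.18, 0.5) (both above threshold); the rest fail at least one
    criterion, a ``missing_fraction`` of those by a missing value.
    ``n_manual_keep`` failing records are flagged for curation-based
    retention.  Truth records the passing and the expected-retained sets.
    """
    if not 0.0 <= pass_fraction <= 1.0:
        raise ValueError("pass_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    herbs = [h for h, c in n_per_herb.items() for _ in range(c)]
    n = len(herbs)
    ids = [f"C{i:04d}" for i in range(1, n + 1)]
    n_pass = int(round(pass_fraction * n))
    pass_idx = set(rng.choice(n, size=n_pass, replace=False).tolist()) if n else set()
    fail_idx = [i for i in range(n) if i not in pass_idx]
    n_manual = min(n_manual_keep, len(fail_idx))
    manual_idx = set(rng.choice(len(fail_idx), size=n_manual, replace=False).tolist())
    manual_ids = {ids[fail_idx[j]] for j in manual_idx}
    records = []
    for i in range(n):
        if i in pass_idx:
            ob: float | None = float(rng.uniform(20.0, 60.0))
            dl: float | None = float(rng.uniform(0.18, 0.5))
        else:
            which = rng.integers(3)  # fail ob, fail dl, or both
            ob = float(rng.uniform(0.0, 20.0)) if which in (0, 2) else float(rng.uniform(20.0, 60.0))
            dl = float(rng.uniform(0.0, 0.18)) if which in (1, 2) else float(rng.uniform(0.18, 0.5))
            if which in (0, 2):
                ob = min(ob, np.nextafter(20.0, 0.0))
            if which in (1, 2):
                dl = min(dl, np.nextafter(0.18, 0.0))
            if rng.random() < missing_fraction:
                if rng.random() < 0.5:
                    ob = None
                else:
                    dl = None
        records.append(ComponentRecord(
            component_id=ids[i], name=f"cmp_{ids[i]}", herb=herbs[i],
            ob=ob, dl=dl, manual_keep=ids[i] in manual_ids))
    passing = {ids[i] for i in pass_idx}
    truth = SyntheticTruth(
        seed=seed,
        params={"n_per_herb": dict(n_per_herb), "pass_fraction": pass_fraction,
                "n_manual_keep": n_manual_keep},
        expected_pass_components=passing,
        expected_retained_components=passing | manual_ids,
    )
    return records, truth


def _power_law_degrees(
    rng: np.random.Generator, n: int, mean_degree: float, exponent: float, d_max: int
) -> np.ndarray:
    """Heavy-tailed degrees on [1, d_max], rescaled to the requested mean."""
    support = np.arange(1, d_max + 1, dtype=float)
    pmf = support ** (-exponent)
    pmf /= pmf.sum()
    raw = rng.choice(support, size=n, p=pmf)
    scaled = raw * (mean_degree / raw.mean())
    return np.clip(np.round(scaled), 1, d_max).astype(int)


def gen_component_target(
    component_ids: list[str],
    targets: int | list[str],
    mean_degree: float,
    heavy_tail_exponent: float = 2.2,
    seed: int = 0,
) -> tuple[ComponentTargetTable, SyntheticTruth]:
    """Bipartite component-target pairs with heavy-tailed component degrees.

    ``targets`` is either a count (symbols ``T0001``...) or an explicit
    label list.  Each component receives a truncated-power-law number of
    distinct targets, rescaled so the sample mean tracks ``mean_degree``;
    any target left uncovered is attached to the highest-degree component
    (degrees in truth reflect the final table).
    """
    rng = np.random.default_rng(seed)
    labels = [f"T{i:04d}" for i in range(1, targets + 1)] if isinstance(targets, int) else list(targets)
    n_t = len(labels)
    if n_t == 0 or not component_ids:
        return ComponentTargetTable(()), SyntheticTruth(seed=seed)
    if n_t == 1:
        pairs = [(cid, labels[0]) for cid in component_ids]
        table = ComponentTargetTable.from_pairs(pairs)
        truth = SyntheticTruth(seed=seed, component_degrees={c: 1 for c in component_ids},
                               formula_targets=set(labels))
        return table, truth
    degrees = _power_law_degrees(rng, len(component_ids), mean_degree,
                                 heavy_tail_exponent, n_t)
    chosen: dict[str, set[str]] = {}
    for cid, d in zip(component_ids, degrees):
        picks = rng.choice(n_t, size=int(d), replace=False)
        chosen[cid] = {labels[j] for j in picks}
    covered = set().union(*chosen.values())
    if len(covered) < n_t:
        sink = max(chosen, key=lambda c: (len(chosen[c]), c))
        chosen[sink] |= set(labels) - covered
    pairs = [(cid, t) for cid in component_ids for t in sorted(chosen[cid])]
    table = ComponentTargetTable.from_pairs(pairs)
    truth = SyntheticTruth(
        seed=seed,
        params={"mean_degree": mean_degree, "heavy_tail_exponent": heavy_tail_exponent},
        component_degrees={c: len(s) for c, s in chosen.items()},
        formula_targets=set(labels),
    )
    return table, truth


def gen_disease_targets(
    universe: list[str],
    n: int,
    overlap_with: TargetSet,
    overlap_fraction: float,
    seed: int = 0,
    force_overlap: tuple[str, ...] = (),
) -> tuple[TargetSet, SyntheticTruth]:
    """Disease target list with an exactly controlled formula overlap.

    Exactly ``round(overlap_fraction * n)`` members come from
    ``overlap_with`` (``force_overlap`` members guaranteed among them); the
    remainder avoids ``overlap_with`` entirely, so the intersection with the
    formula set is known in advance.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_overlap = int(round(overlap_fraction * n))
    pool_in = sorted(overlap_with.members)
    forced = [f for f in force_overlap]
    if any(f not in overlap_with.members for f in forced):
        raise ValueError("force_overlap members must belong to overlap_with")
    if n_overlap > len(pool_in):
        raise ValueError("overlap_fraction*n exceeds |overlap_with|")
    free = [s for s in pool_in if s not in set(forced)]
    extra = rng.choice(len(free), size=n_overlap - len(forced), replace=False)
    overlap = set(forced) | {free[j] for j in extra}
    pool_out = sorted(set(universe) - overlap_with.members)
    n_out = n - n_overlap
    if n_out > len(pool_out):
        raise ValueError("universe too small for the requested disjoint part")
    out_idx = rng.choice(len(pool_out), size=n_out, replace=False)
    members = overlap | {pool_out[j] for j in out_idx}
    truth = SyntheticTruth(
        seed=seed,
        params={"n": n, "overlap_fraction": overlap_fraction},
        disease_targets=members,
        expected_common=overlap,
    )
    return TargetSet("disease", frozenset(members)), truth


def gen_interactome(
    n: int,
    attachment: int,
    planted_modules: list[tuple[int, float]] = (),
    n_hubs: int = 0,
    planted_hub_degree: int = 0,
    seed: int = 0,
) -> tuple[nx.Graph, SyntheticTruth]:
    """Scale-free interactome with planted dense modules and planted hubs.

    The backbone is preferential attachment on ``n`` nodes (``attachment``
    edges per arrival) grown from an ``attachment``-clique, giving exactly
    C(m,2) + m*(n-m) backbone edges.  Each planted module draws its
    internal edges independently with probability ``p_intra`` over a
    disjoint random node set; backbone edges running between two different
    modules are removed so module membership is a well-posed ground truth
    (planted-partition semantics — modules stay wired to the background,
    just not directly to each other).  Hubs are drawn from the first module
    when one exists (a dense neighborhood makes them dominant on
    triangle-based statistics too) and wired to ``planted_hub_degree``
    random nodes.
    """
    rng = np.random.default_rng(seed)
    m = attachment
    backbone = nx.barabasi_albert_graph(
        n, m, seed=int(rng.integers(2**31)), initial_graph=nx.complete_graph(m))
    width = max(4, len(str(n)))
    names = {i: f"G{i:0{width}d}" for i in backbone.nodes}
    g = nx.relabel_nodes(backbone, names)
    nodes = sorted(g.nodes)
    taken: set[str] = set()
    modules: list[tuple[tuple[str, ...], float]] = []
    for size, p_intra in planted_modules:
        pool = [v for v in nodes if v not in taken]
        idx = rng.choice(len(pool), size=size, replace=False)
        members = sorted(pool[j] for j in idx)
        for prev, _ in modules:  # planted-partition: no direct module-module edges
            g.remove_edges_from([(u, v) for u in members for v in prev
                                 if g.has_edge(u, v)])
        taken |= set(members)
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                if rng.random() < p_intra:
                    g.add_edge(u, v)
        modules.append((tuple(members), p_intra))
    hubs: list[str] = []
    if n_hubs:
        pool = list(modules[0][0]) if modules else nodes
        idx = rng.choice(len(pool), size=n_hubs, replace=False)
        hubs = sorted(pool[j] for j in idx)
        for h in hubs:
            others = [v for v in nodes if v != h]
            idx = rng.choice(len(others), size=min(planted_hub_degree, len(others)),
                             replace=False)
            g.add_edges_from((h, others[j]) for j in idx)
    nx.set_node_attributes(g, "interactor", "role")
    truth = SyntheticTruth(
        seed=seed,
        params={"n": n, "attachment": m, "planted_modules": list(planted_modules),
                "n_hubs": n_hubs, "planted_hub_degree": planted_hub_degree},
        planted_modules=modules,
        planted_hubs=set(hubs),
    )
    return g, truth


def gen_annotations(
    n_terms: int,
    size_range: tuple[int, int],
    universe: list[str],
    spike: tuple[str, float] | None = None,
    query: int | list[str] = 0,
    seed: int = 0,
) -> tuple[AnnotationCollection, TargetSet, SyntheticTruth]:
    """GMT-style collection with one optionally spiked enriched term.

    ``query`` is either a size (drawn uniformly from the universe) or an
    explicit gene list.  ``spike = (term_id, strength)`` rebuilds the spiked
    term so a ``strength`` fraction of the query lies inside it (random
    genes fill it to its drawn size); at strength 1 the spiked term contains
    the whole query and attains the minimal p against it.
    """
    rng = np.random.default_rng(seed)
    uni = sorted(universe)
    lo, hi = size_range
    terms: dict[str, tuple[str, list[str]]] = {}
    for i in range(1, n_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(uni), size=size, replace=False)
        tid = f"TERM{i:04d}"
        terms[tid] = (f"synthetic term {i}", [uni[j] for j in idx])
    if isinstance(query, int):
        q_idx = rng.choice(len(uni), size=query, replace=False) if query else []
        query_members = {uni[j] for j in q_idx}
    else:
        query_members = set(query)
    spiked = None
    if spike is not None:
        spiked, strength = spike
        if spiked not in terms:
            raise ValueError(f"spiked term {spiked!r} not among generated terms")
        if not 0.0 <= strength <= 1.0:
            raise ValueError("spike strength must be in [0, 1]")
        q_sorted = sorted(query_members)
        n_in = int(round(strength * len(q_sorted)))
        idx = rng.choice(len(q_sorted), size=n_in, replace=False)
        inside = [q_sorted[j] for j in idx]
        size = max(len(terms[spiked][1]), n_in)
        pool = [u for u in uni if u not in query_members]
        idx = rng.choice(len(pool), size=size - n_in, replace=False)
        terms[spiked] = (terms[spiked][0], inside + [pool[j] for j in idx])
    ann = AnnotationCollection.from_terms(terms)
    truth = SyntheticTruth(
        seed=seed,
        params={"n_terms": n_terms, "size_range": list(size_range), "spike": spike and list(spike)},
        spiked_term=spiked,
    )
    return ann, TargetSet("query", frozenset(query_members)), truth


# ---------------------------------------------------------------------------
# Study-shaped preset

PAPER_SHAPED = {
    "herbs": {"Mahuang": 230, "Xingren": 85, "Gancao": 280, "Shigao": 5},
    "pass_fraction": 0.22,          # 132/600 pass the OB/DL filter ...
    "n_manual_keep": 9,             # ... plus 9 curated keeps -> 141
    "n_with_targets": 118,          # components that received target predictions
    "n_formula_targets": 186,
    "mean_degree": 21.0,
    "heavy_tail_exponent": 2.2,
    "n_disease": 546,
    "n_common": 52,
    "n_disease_sources": 5,
    "interactome_n": 1500,
    "attachment": 3,
    "planted_modules": [(40, 0.6), (12, 0.9), (12, 0.9)],
    "n_hubs": 1,
    "planted_hub_degree": 300,
    "n_terms": 50,
    "term_size_range": (10, 80),
    "spike_strength": 0.9,
}


def paper_shaped(seed: int, out_dir: str | Path | None = None):
    """Generate the full study-shaped fixture; optionally write it to disk.

    Returns ``(artifacts, truth)`` where ``artifacts`` maps input names to
    in-memory objects (and to file paths when ``out_dir`` is given).
    """
    p = PAPER_SHAPED
    records, t_cmp = gen_components(
        p["herbs"], p["pass_fraction"], derive_seed(seed, "components"),
        n_manual_keep=p["n_manual_keep"])
    retained = sorted(t_cmp.expected_retained_components)

    interactome, t_net = gen_interactome(
        p["interactome_n"], p["attachment"], p["planted_modules"],
        n_hubs=p["n_hubs"], planted_hub_degree=p["planted_hub_degree"],
        seed=derive_seed(seed, "interactome"))
    hub = sorted(t_net.planted_hubs)[0]
    module1 = list(t_net.planted_modules[0][0])

    # formula targets: the hub, its dense module, and random interactome nodes
    rng = np.random.default_rng(derive_seed(seed, "pairs"))
    base = sorted(set([hub] + module1))
    pool = sorted(set(interactome.nodes) - set(base))
    idx = rng.choice(len(pool), size=p["n_formula_targets"] - len(base), replace=False)
    target_labels = sorted(base + [pool[j] for j in idx])
    with_targets = sorted(rng.choice(retained, size=min(p["n_with_targets"], len(retained)),
                                     replace=False).tolist())
    pairs, t_pairs = gen_component_target(
        with_targets, target_labels, p["mean_degree"], p["heavy_tail_exponent"],
        seed=derive_seed(seed, "pairs"))
    formula = pairs.target_set("formula")

    disease, t_dis = gen_disease_targets(
        sorted(interactome.nodes), p["n_disease"], formula,
        overlap_fraction=p["n_common"] / p["n_disease"],
        seed=derive_seed(seed, "disease"), force_overlap=(hub,))

    # the spiked query is the planted dense hub module: the nodes the core
    # screen is expected to recover, so the pipeline-level enrichment has a
    # designed positive
    ann, spike_query, t_ann = gen_annotations(
        p["n_terms"], p["term_size_range"], sorted(interactome.nodes),
        spike=("TERM0001", p["spike_strength"]),
        query=sorted(set([hub] + module1)),
        seed=derive_seed(seed, "annotations"))

    truth = SyntheticTruth(
        seed=seed,
        params=dict(p, planted_modules=[list(x) for x in p["planted_modules"]],
                    term_size_range=list(p["term_size_range"])),
        expected_pass_components=t_cmp.expected_pass_components,
        expected_retained_components=t_cmp.expected_retained_components,
        component_degrees=t_pairs.component_degrees,
        formula_targets=set(formula.members),
        disease_targets=set(disease.members),
        expected_common=t_dis.expected_common,
        planted_modules=t_net.planted_modules,
        planted_hubs=t_net.planted_hubs,
        spiked_term=t_ann.spiked_term,
    )

    # disease members split over emulated sources (round-robin; union intact)
    sources: list[list[str]] = [[] for _ in range(p["n_disease_sources"])]
    for i, s in enumerate(sorted(disease.members)):
        sources[i % p["n_disease_sources"]].append(s)
        if i % 17 == 0:  # some cross-source duplication, as real databases show
            sources[(i + 1) % p["n_disease_sources"]].append(s)

    artifacts = {
        "components": records, "pairs": pairs, "disease": disease,
        "disease_sources": sources, "interactome": interactome,
        "annotations": ann, "spike_query": spike_query,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_component_table(records, out / "components.tsv")
        write_pair_table(pairs, out / "component_targets.tsv")
        for i, src in enumerate(sources, start=1):
            write_gene_list(src, out / f"disease_source_{i}.tsv")
        write_network(interactome, out / "interactome.tsv", format="tsv")
        write_gmt(ann, out / "annotations.gmt")
        write_gene_list(sorted(spike_query.members), out / "spiked_query.tsv")
        truth.to_json(out / "truth.json")
        artifacts["paths"] = {
            "components": str(out / "components.tsv"),
            "pairs": str(out / "component_targets.tsv"),
            "disease": [str(out / f"disease_source_{i}.tsv")
                        for i in range(1, p["n_disease_sources"] + 1)],
            "interactome": str(out / "interactome.tsv"),
            "gmt": str(out / "annotations.gmt"),
            "truth": str(out / "truth.json"),
        }
    return artifacts, truth
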