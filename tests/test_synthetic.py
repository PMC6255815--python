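import networkx as nx
import numpy as np
import pytest

from netpharm.adme import screen_bioactive
from netpharm.enrich import enrich
from netpharm.graphio import canonical_edges
from netpharm.synthetic import (derive_seed, gen_annotations, gen_components,
                                gen_component_target, gen_disease_targets,
                                gen_interactome, paper_shaped)
from netpharm.targets import TargetSet, intersect_targets


def test_pass_fraction_extremes():
    all_pass, truth = gen_components({"H": 50}, 1.0, seed=1)
    assert {r.component_id for r in screen_bioactive(all_pass)} == \
        truth.expected_pass_components
    assert len(truth.expected_pass_components) == 50
    none_pass, truth0 = gen_components({"H": 50}, 0.0, seed=1)
    assert screen_bioactive(none_pass) == []
    assert truth0.expected_pass_components == set()


def test_screen_recovers_planted_pass_set():
    records, truth = gen_components(
        {"A": 230, "B": 85, "C": 280, "D": 5}, 0.235, seed=7, n_manual_keep=9)
    kept = {r.component_id for r in screen_bioactive(records)}
    assert kept == truth.expected_retained_components
    assert len(truth.expected_pass_components) == round(0.235 * 600)
    no_manual = {r.component_id for r in screen_bioactive(records, keep_manual=False)}
    assert no_manual == truth.expected_pass_components


def test_components_deterministic():
    a, _ = gen_components({"H": 100}, 0.3, seed=5, n_manual_keep=3)
    b, _ = gen_components({"H": 100}, 0.3, seed=5, n_manual_keep=3)
    assert a == b


def test_component_target_degenerate_single_target():
    table, _ = gen_component_target(["c1", "c2", "c3"], 1, mean_degree=5, seed=1)
    assert {t for _, t in table.pairs} == {"T0001"}


def test_component_target_mean_degree_honored():
    ids = [f"c{i}" for i in range(150)]
    table, truth = gen_component_target(ids, 400, mean_degree=12, seed=3)
    mean = np.mean(list(truth.component_degrees.values()))
    assert abs(mean - 12) / 12 < 0.10
    # truth degrees equal realized degrees in the table
    from collections import Counter
    realized = Counter(c for c, _ in table.pairs)
    assert dict(realized) == truth.component_degrees


def test_component_target_deterministic():
    a, _ = gen_component_target(["c1", "c2"], 20, 4, seed=9)
    b, _ = gen_component_target(["c1", "c2"], 20, 4, seed=9)
    assert a == b


def test_disease_overlap_exact():
    universe = [f"G{i:03d}" for i in range(400)]
    formula = TargetSet("formula", frozenset(universe[:100]))
    disease, truth = gen_disease_targets(universe, 150, formula, 0.2, seed=4)
    inter = intersect_targets(formula, disease)
    assert inter.members == frozenset(truth.expected_common)
    assert len(inter) == round(0.2 * 150)
    assert len(disease) == 150


def test_disease_overlap_extremes():
    universe = [f"G{i:03d}" for i in range(300)]
    formula = TargetSet("formula", frozenset(universe[:80]))
    none, _ = gen_disease_targets(universe, 50, formula, 0.0, seed=1)
    assert not (none.members & formula.members)
    full, _ = gen_disease_targets(universe, 50, formula, 1.0, seed=1)
    assert len(full.members & formula.members) == 50


def test_interactome_backbone_edge_count():
    g, _ = gen_interactome(500, 3, seed=2)
    assert g.number_of_edges() == 3 + 3 * 497  # triangle start + 3 per arrival


def test_planted_clique_present():
    g, truth = gen_interactome(200, 2, planted_modules=[(6, 1.0)], seed=3)
    members, p = truth.planted_modules[0]
    assert p == 1.0
    sub = g.subgraph(members)
    assert sub.number_of_edges() == 15  # K6


def test_planted_hub_degree():
    g, truth = gen_interactome(300, 2, planted_modules=[(10, 0.8)],
                               n_hubs=1, planted_hub_degree=120, seed=4)
    (hub,) = truth.planted_hubs
    assert g.degree(hub) >= 120
    assert hub in truth.planted_modules[0][0]


def test_interactome_deterministic():
    a, _ = gen_interactome(150, 2, planted_modules=[(8, 0.5)], n_hubs=1,
                           planted_hub_degree=40, seed=6)
    b, _ = gen_interactome(150, 2, planted_modules=[(8, 0.5)], n_hubs=1,
                           planted_hub_degree=40, seed=6)
    assert canonical_edges(a) == canonical_edges(b)


def test_spiked_term_attains_minimal_p():
    universe = [f"G{i:03d}" for i in range(300)]
    ann, query, truth = gen_annotations(
        30, (10, 30), universe, spike=("TERM0007", 1.0), query=20, seed=8)
    assert truth.spiked_term == "TERM0007"
    rows = enrich(query, ann)
    assert rows[0].term_id == "TERM0007"
    assert rows[0].p_raw == min(r.p_raw for r in rows)


def test_no_spike_keeps_query_unplanted():
    ann, query, truth = gen_annotations(10, (5, 15),
                                        [f"G{i:03d}" for i in range(100)],
                                        query=10, seed=9)
    assert truth.spiked_term is None
    assert len(query.members) == 10


def test_annotation_determinism():
    args = dict(n_terms=12, size_range=(5, 20),
                universe=[f"G{i:03d}" for i in range(80)],
                spike=("TERM0002", 0.8), query=10, seed=11)
    a1, q1, _ = gen_annotations(**args)
    a2, q2, _ = gen_annotations(**args)
    assert a1.terms == a2.terms and q1 == q2


def test_derive_seed_stable_and_bounded():
    assert derive_seed(42, "pairs") == derive_seed(42, "pairs")
    assert derive_seed(42, "pairs") != derive_seed(42, "disease")
    assert 0 <= derive_seed(7, "interactome") < 2**31


def test_paper_shaped_counts(tmp_path):
    arts, truth = paper_shaped(11, out_dir=tmp_path / "fix")
    assert len(truth.expected_retained_components) == 141
    assert len(truth.formula_targets) == 186
    assert len(truth.disease_targets) == 546
    assert len(truth.expected_common) == 52
    assert truth.planted_hubs <= truth.formula_targets
    assert (tmp_path / "fix" / "truth.json").exists()
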