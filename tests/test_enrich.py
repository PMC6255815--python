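from itertools import product

import pytest
from scipy.stats import hypergeom

import oracles
from netpharm.enrich import (AnnotationCollection, enrich, filter_significant,
                             hypergeom_tail, read_gmt, write_gmt)
from netpharm.targets import TargetSet


def ann_from(terms, background=None):
    return AnnotationCollection.from_terms(terms, background)


def q(*members):
    return TargetSet("query", frozenset(members))


def test_gmt_parse_and_background_default(tmp_path):
    p = tmp_path / "a.gmt"
    p.write_text("T1\tfirst\tA\tB\tC\nT2\tsecond\tC\tD\tE\tF\n")
    ann = read_gmt(p)
    assert set(ann.terms) == {"T1", "T2"}
    assert ann.background_size == 6  # |union| with one shared gene


def test_gmt_round_trip(tmp_path):
    ann = ann_from({"T1": ("one", {"A", "B"}), "T2": ("two", {"B", "C", "D"})})
    p = tmp_path / "a.gmt"
    write_gmt(ann, p)
    back = read_gmt(p)
    assert back.terms == ann.terms and back.background_size == ann.background_size


def test_gmt_short_row_raises(tmp_path):
    p = tmp_path / "bad.gmt"
    p.write_text("T1\tonly-description\n")
    with pytest.raises(Exception, match=":1"):
        read_gmt(p)


def test_background_smaller_than_largest_term_rejected():
    with pytest.raises(ValueError):
        ann_from({"T1": ("one", {"A", "B", "C"})}, background=2)


def test_full_overlap_closed_form():
    # N=20, K=5, n=5, k=5: P = 1/C(20,5) = 1/15504
    assert hypergeom_tail(20, 5, 5, 5) == pytest.approx(1 / 15504, abs=1e-12)


def test_zero_overlap_gives_one():
    assert hypergeom_tail(20, 5, 5, 0) == 1.0
    assert hypergeom_tail(20, 5, 5, -1) == 1.0


def test_tail_matches_exhaustive_enumeration_N8():
    for K, n in product(range(1, 9), range(1, 9)):
        for k in range(0, min(K, n) + 1):
            got = hypergeom_tail(8, K, n, k)
            want = oracles.hypergeom_tail_oracle(8, K, n, k)
            assert got == pytest.approx(want, abs=1e-12), (K, n, k)


def test_pmf_sums_to_one():
    for N, K, n in [(8, 3, 4), (20, 5, 5), (50, 10, 7)]:
        total = sum(float(hypergeom.pmf(k, N, K, n)) for k in range(0, min(K, n) + 1))
        assert total == pytest.approx(1.0, abs=1e-12)


def test_tail_non_increasing_in_k():
    vals = [hypergeom_tail(30, 8, 10, k) for k in range(0, 9)]
    assert all(a >= b for a, b in zip(vals, vals[1:]))


def make_collection():
    return ann_from({
        "T1": ("hit", {"A", "B", "C", "D"}),
        "T2": ("miss", {"E", "F", "G"}),
        "T3": ("partial", {"A", "H", "I", "J", "K"}),
    }, background=20)


def test_enrich_rows_sorted_and_counted():
    rows = enrich(q("A", "B", "C"), make_collection())
    assert [r.term_id for r in rows] == ["T1", "T3", "T2"]
    top = rows[0]
    assert (top.k, top.K, top.n, top.N) == (3, 4, 3, 20)
    assert top.p_raw == pytest.approx(
        oracles.hypergeom_tail_oracle(20, 4, 3, 3), abs=1e-12)
    assert top.overlap_members == frozenset("ABC")


def test_bonferroni_counts_overlapping_terms_only():
    rows = enrich(q("A", "B", "C"), make_collection())
    by_id = {r.term_id: r for r in rows}
    # T1 and T3 overlap -> multiplier 2
    assert by_id["T1"].p_bonferroni == pytest.approx(min(1.0, by_id["T1"].p_raw * 2))
    rows_all = enrich(q("A", "B", "C"), make_collection(), bonferroni_all_terms=True)
    by_id_all = {r.term_id: r for r in rows_all}
    assert by_id_all["T1"].p_bonferroni == pytest.approx(min(1.0, by_id["T1"].p_raw * 3))


def test_ease_never_smaller_than_hypergeometric():
    coll = make_collection()
    for query in [q("A", "B", "C"), q("A"), q("E", "F", "G", "H")]:
        hyp = {r.term_id: r.p_raw for r in enrich(query, coll)}
        ease = {r.term_id: r.p_raw for r in enrich(query, coll, mode="ease")}
        for tid in hyp:
            assert ease[tid] >= hyp[tid] - 1e-15
    # k=1 in ease mode discounts to 0 -> p = 1
    row = [r for r in enrich(q("A"), coll, mode="ease") if r.term_id == "T1"][0]
    assert row.p_raw == 1.0


def test_query_outside_background_dropped():
    rows = enrich(q("A", "ZZZ"), make_collection())
    assert rows[0].n == 1  # ZZZ is not annotated anywhere
    assert enrich(q("ZZZ"), make_collection()) == []


def test_filter_significant_strictness():
    rows = enrich(q("A", "B", "C", "D"), make_collection())
    sig = filter_significant(rows, "bonferroni_lt", alpha=0.05)
    assert all(r.p_bonferroni < 0.05 for r in sig)
    # strict boundary: a row at exactly alpha is dropped
    at_alpha = [r for r in rows if r.p_raw >= 0.05]
    assert all(r not in filter_significant(rows, "raw_lt", 0.05) for r in at_alpha)
    with pytest.raises(ValueError):
        filter_significant(rows, alpha=0.0)
    with pytest.raises(ValueError):
        filter_significant(rows, criterion="fdr")
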