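"""Over-representation analysis with Bonferroni control.

Given a query gene set and a term -> gene-set annotation collection (GMT),
each term is scored by the upper hypergeometric tail: with background size
N, term size K, query size n and overlap k,

    p_raw = P(X >= k),   X ~ Hypergeometric(N, K, n).

The EASE variant discounts one overlap member (k -> k-1, floored at 0,
where k = 0 gives p = 1), the conservative score used by DAVID-style
annotation tools.  Bonferroni-adjusted p multiplies the raw p by the number
of terms with nonzero overlap (DAVID-style reporting; the total-term
multiplier is available), capped at 1.  The background defaults to the
union of all annotated genes and can be overridden (e.g. to the
interactome size).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from scipy.stats import hypergeom

from .graphio import ParseError, normalize_symbol
from .targets import TargetSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationCollection:
    """term_id -> (name, member genes) with an explicit background size."""

    terms: dict[str, tuple[str, frozenset[str]]]
    background_size: int

    def __post_init__(self):
        largest = max((len(g) for _, g in self.terms.values()), default=0)
        if self.background_size < largest:
            raise ValueError("background_size smaller than the largest term")

    @classmethod
    def from_terms(cls, terms, background_size: int | None = None) -> "AnnotationCollection":
        norm = {
            tid: (name, frozenset(normalize_symbol(g) for g in genes))
            for tid, (name, genes) in terms.items()
        }
        if background_size is None:
            universe: set[str] = set()
            for _, genes in norm.values():
                universe |= genes
            background_size = len(universe)
        return cls(norm, background_size)

    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.terms.values():
            out |= genes
        return frozenset(out)


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    name: str
    k: int  # overlap count
    K: int  # term size
    n: int  # query size (within background)
    N: int  # background size
    p_raw: float
    p_bonferroni: float
    overlap_members: frozenset[str]


def read_gmt(path: str | Path, background_size: int | None = None) -> AnnotationCollection:
    """Read a GMT file: term_id <tab> description <tab> gene1 ... geneN."""
    path = Path(path)
    terms: dict[str, tuple[str, list[str]]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT row needs >=3 fields")
            genes = [g for g in fields[2:] if g.strip()]
            if not genes:
                raise ParseError(f"{path}:{lineno}: term {fields[0]!r} has no genes")
            terms[fields[0].strip()] = (fields[1].strip(), genes)
    return AnnotationCollection.from_terms(terms, background_size)


def write_gmt(ann: AnnotationCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for tid in sorted(ann.terms):
            name, genes = ann.terms[tid]
            fh.write("\t".join([tid, name, *sorted(genes)]) + "\n")


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); 1.0 when k <= 0."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: TargetSet,
    ann: AnnotationCollection,
    mode: str = "hypergeometric",
    bonferroni_all_terms: bool = False,
) -> list[EnrichmentRow]:
    """Score every term against the query; rows sorted p-ascending.

    Query members outside the annotation universe are dropped (count
    logged).  ``mode="ease"`` discounts one overlap member before taking
    the tail.  The Bonferroni multiplier counts terms with k >= 1 unless
    ``bonferroni_all_terms``.
    """
    if mode not in ("hypergeometric", "ease"):
        raise ValueError(f"unknown enrichment mode: {mode!r}")
    universe = ann.universe()
    inside = query.members & universe
    dropped = len(query.members) - len(inside)
    if dropped:
        logger.info("enrich: dropped %d query member(s) outside the background", dropped)
    n = len(inside)
    if n == 0:
        logger.warning("enrich: empty query after background filtering")
        return []
    N = ann.background_size
    raw: list[tuple[str, str, int, int, float, frozenset[str]]] = []
    n_overlapping = 0
    for tid in sorted(ann.terms):
        name, genes = ann.terms[tid]
        overlap = inside & genes
        k = len(overlap)
        if k >= 1:
            n_overlapping += 1
        k_eff = k - 1 if mode == "ease" else k
        p = hypergeom_tail(N, len(genes), n, k_eff)
        raw.append((tid, name, k, len(genes), p, frozenset(overlap)))
    multiplier = len(ann.terms) if bonferroni_all_terms else n_overlapping
    rows = [
        EnrichmentRow(tid, name, k, K, n, N, p, min(1.0, p * multiplier), overlap)
        for tid, name, k, K, p, overlap in raw
    ]
    rows.sort(key=lambda r: (r.p_raw, r.term_id))
    return rows


def filter_significant(
    rows: list[EnrichmentRow],
    criterion: str = "bonferroni_lt",
    alpha: float = 0.05,
) -> list[EnrichmentRow]:
    """Keep rows with the chosen p strictly below alpha."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if criterion == "bonferroni_lt":
        return [r for r in rows if r.p_bonferroni < alpha]
    if criterion == "raw_lt":
        return [r for r in rows if r.p_raw < alpha]
    raise ValueError(f"unknown criterion: {criterion!r}")


def write_enrichment(rows: list[EnrichmentRow], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("term_id\tname\tk\tK\tn\tN\tp_raw\tp_bonferroni\toverlap\n")
        for r in rows:
            fh.write(f"{r.term_id}\t{r.name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                     f"{r.p_raw:.6e}\t{r.p_bonferroni:.6e}\t"
                     f"{','.join(sorted(r.overlap_members))}\n")
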