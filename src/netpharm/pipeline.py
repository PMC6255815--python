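"""End-to-end pipeline: screen -> targets -> ppi -> centrality -> core-screen
-> cluster -> enrich, with a machine-readable run report.

Every stage artifact is materialized in the output directory (auditable
multi-stage screening), and the report's count trail is re-derivable from
those artifacts.  Given identical inputs, configuration and seed the run is
byte-identical (no timestamps in artifacts).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .adme import read_component_table, screen_bioactive, write_component_table
from .centrality import DEFAULT_MEASURES, compute_all
from .enrich import enrich, filter_significant, read_gmt, write_enrichment
from .graphio import read_edge_list, read_gene_list, write_gene_list, write_network
from .mcode import McodeParams, find_clusters, write_clusters
from .ppi import SeedExpansionPolicy, expand_seeds, intersect_networks, union_networks
from .screen import run_screen
from .targets import (TargetSet, build_bipartite, candidate_components,
                      intersect_targets, read_pair_table, union_targets)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    # input paths
    components: str = ""
    pairs: str = ""
    disease: list[str] = field(default_factory=list)
    interactome: str = ""
    gmt: str = ""
    # adme
    ob_min: float = 20.0
    dl_min: float = 0.18
    keep_manual: bool = True
    # targets
    candidate_min_degree: str | float = "median"
    # ppi
    hops: int = 1
    include_neighbor_edges: bool = True
    merge: str = "intersect"  # or "union"
    drop_isolated: bool = True
    # core screen
    multiplier: float = 2.0
    stage2_rule: str = "median"  # or "explicit"
    stage2_cutoffs: dict[str, float] | None = None
    measures: list[str] = field(default_factory=lambda: list(DEFAULT_MEASURES))
    # mcode
    mcode: dict = field(default_factory=dict)
    # enrichment
    enrich_mode: str = "hypergeometric"
    enrich_criterion: str = "bonferroni_lt"
    alpha: float = 0.05
    # run
    seed: int = 0
    out_dir: str = "pipeline_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns the run report (also written as
    ``report.json``).  Any stage error aborts with the stage name; partial
    artifacts are retained."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"tool": "netpharm", "version": __version__,
                    "seed": config.seed,
                    "config": {k: v for k, v in dataclasses.asdict(config).items()},
                    "stages": {}}
    stage = "adme_screen"
    try:
        records = read_component_table(config.components)
        bioactive = screen_bioactive(records, config.ob_min, config.dl_min,
                                     config.keep_manual)
        write_component_table(bioactive, out / "bioactive.tsv")
        report["stages"]["adme_screen"] = {
            "components_in": len(records), "bioactive": len(bioactive)}

        stage = "target_mapping"
        pairs = read_pair_table(config.pairs)
        bioactive_ids = {r.component_id for r in bioactive}
        pairs = type(pairs).from_pairs(
            [(c, t) for c, t in pairs.pairs if c in bioactive_ids])
        formula = pairs.target_set("formula")
        sources = [TargetSet.from_symbols(Path(p).stem, read_gene_list(p))
                   for p in config.disease]
        disease = union_targets(sources, label="disease")
        common = intersect_targets(formula, disease)
        bip = build_bipartite(pairs)
        cands = candidate_components(bip, config.candidate_min_degree)
        write_gene_list(sorted(formula.members), out / "formula_targets.tsv")
        write_gene_list(sorted(disease.members), out / "disease_union.tsv")
        write_gene_list(sorted(common.members), out / "common_targets.tsv")
        write_network(bip, out / "bipartite.graphml", format="graphml")
        with (out / "candidates.tsv").open("w") as fh:
            fh.write("component_id\tdegree\n")
            for cid, d in cands:
                fh.write(f"{cid}\t{d}\n")
        report["stages"]["target_mapping"] = {
            "pairs": len(pairs.pairs),
            "components_with_targets": len(pairs.components()),
            "formula_targets": len(formula),
            "disease_sources": {s.label: len(s) for s in sources},
            "disease_union": len(disease),
            "common_targets": len(common),
            "bipartite_nodes": bip.number_of_nodes(),
            "bipartite_edges": bip.number_of_edges(),
            "candidate_components": len(cands),
        }

        stage = "ppi_assembly"
        interactome = read_edge_list(config.interactome)
        policy = SeedExpansionPolicy(config.include_neighbor_edges, config.hops)
        net_f = expand_seeds(interactome, formula, policy)
        net_d = expand_seeds(interactome, disease, policy)
        if config.merge == "intersect":
            inter = intersect_networks(net_f, net_d, config.drop_isolated)
        elif config.merge == "union":
            inter = union_networks(net_f, net_d)
        else:
            raise ValueError(f"unknown merge mode: {config.merge!r}")
        write_network(net_f, out / "formula_ppi.graphml", format="graphml")
        write_network(net_d, out / "disease_ppi.graphml", format="graphml")
        write_network(inter, out / "merged_ppi.graphml", format="graphml")
        report["stages"]["ppi_assembly"] = {
            "interactome_nodes": interactome.number_of_nodes(),
            "interactome_edges": interactome.number_of_edges(),
            "formula_ppi": [net_f.number_of_nodes(), net_f.number_of_edges()],
            "disease_ppi": [net_d.number_of_nodes(), net_d.number_of_edges()],
            "merged_ppi": [inter.number_of_nodes(), inter.number_of_edges()],
        }

        stage = "core_screen"
        result = run_screen(inter, multiplier=config.multiplier,
                            rule=config.stage2_rule, explicit=config.stage2_cutoffs,
                            measures=tuple(config.measures))
        if result.stage1_network.number_of_nodes():
            table = compute_all(result.stage1_network, tuple(config.measures))
            table.to_csv(out / "centrality.tsv", sep="\t")
        write_network(result.stage1_network, out / "stage1.graphml", format="graphml")
        write_network(result.core_network, out / "core.graphml", format="graphml")
        write_gene_list(sorted(result.core_nodes), out / "core_targets.tsv")
        with (out / "screen.json").open("w") as fh:
            json.dump({"stage1_threshold": result.stage1_threshold,
                       "stage2_cutoffs": result.stage2_thresholds,
                       "stage1_nodes": result.stage1_network.number_of_nodes(),
                       "core_nodes": len(result.core_nodes)},
                      fh, indent=1, sort_keys=True)
        report["stages"]["core_screen"] = {
            "stage1_threshold": result.stage1_threshold,
            "stage1_nodes": result.stage1_network.number_of_nodes(),
            "stage1_edges": result.stage1_network.number_of_edges(),
            "stage2_cutoffs": result.stage2_thresholds,
            "core_nodes": len(result.core_nodes),
            "core_edges": result.core_network.number_of_edges(),
        }

        stage = "mcode_cluster"
        params = McodeParams(**config.mcode)
        clusters = find_clusters(result.core_network, params=params)
        write_clusters(clusters, out / "clusters.tsv")
        report["stages"]["mcode_cluster"] = {
            "n_clusters": len(clusters),
            "clusters": [{"size": c.size, "score": round(c.score, 6), "seed": c.seed}
                         for c in clusters],
        }

        stage = "enrichment"
        if config.gmt:
            ann = read_gmt(config.gmt)
            rows = enrich(TargetSet("core", frozenset(result.core_nodes)), ann,
                          mode=config.enrich_mode)
            sig = filter_significant(rows, config.enrich_criterion, config.alpha)
            write_enrichment(rows, out / "enrichment.tsv")
            write_enrichment(sig, out / "enrichment_significant.tsv")
            report["stages"]["enrichment"] = {
                "terms_tested": len(rows),
                "significant": len(sig),
                "top_term": sig[0].term_id if sig else None,
            }
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    with (out / "report.json").open("w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
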