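"""End-to-end orchestration over seed-list combinations.

Mirrors the incremental design of the analysis: reference modules are
computed for each seed list alone and for their cumulative unions
(e.g. expression; expression+snp; expression+snp+drug;
expression+snp+drug+omim), each combination is characterised by term
enrichment, and optionally a focal gene set is tested against each
combination's seeds. One set of stochastic partitions is shared across all
combinations, so reruns with the same configuration are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import consensus, focal as focal_mod, stats
from .network import (FocalSet, PPINetwork, SeedGeneList, giant_component,
                      load_edge_list, load_gene_list, simplify)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "combine_seed_lists", "run_analysis", "validate_against_list"]


@dataclass
class AnalysisConfig:
    """Everything needed for a reproducible run.

    ``combinations`` lists the seed-source combinations to analyse, each a
    list of source labels referring to ``seed_lists`` keys.
    """

    network: str
    seed_lists: dict  # source label -> path
    combinations: list = field(default_factory=list)
    annotation: str | None = None  # GMT path for term enrichment
    focal: str | None = None  # focal gene list path
    k: int = 125
    n_runs: int = 100
    alpha_module: float = 0.05
    alpha_term: float = 0.001
    n_resamples: int = 1000
    edge_fraction: float = 0.2
    base_seed: int = 17

    def __post_init__(self) -> None:
        for name, a in (("alpha_module", self.alpha_module),
                        ("alpha_term", self.alpha_term)):
            if not 0 < a < 1:
                raise ValueError(f"{name}={a} outside (0, 1)")
        if not self.combinations:
            # default: each list alone plus the cumulative unions, in the
            # declared order of seed_lists
            labels = list(self.seed_lists)
            self.combinations = [[l] for l in labels]
            for i in range(2, len(labels) + 1):
                self.combinations.append(labels[:i])

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def combine_seed_lists(lists: list[SeedGeneList]) -> SeedGeneList:
    """Set union of seed lists; the label records the constituents."""
    if not lists:
        raise ValueError("need at least one seed list")
    if len(lists) == 1:
        return lists[0]
    genes = set()
    for sl in lists:
        genes |= sl.genes
    label = "union(" + ",".join(sorted(sl.source_label for sl in lists)) + ")"
    if not genes:
        logger.warning("union of seed lists is empty")
    return SeedGeneList(genes=genes, source_label=label)


def validate_against_list(modules: list, validation: SeedGeneList,
                          net: PPINetwork, adjusted_alpha: float = 0.1):
    """Test previously found reference modules for enrichment in a held-out list.

    Used with a consolidated-knowledge gene list (e.g. OMIM disease genes)
    as a validation layer: each reference module gets a hypergeometric
    upper-tail p, BH-adjusted across modules, flagged at the adjusted-p
    threshold (default 0.1).
    """
    val = validation.restricted_to(net)
    rows = []
    for i, m in enumerate(modules):
        k = len(m.nodes & val.genes)
        q = stats.HypergeomQuery(N=net.n_nodes, K=len(val.genes), n=m.size, k=k)
        rows.append({"module": i, "size": m.size, "k": k,
                     "p": stats.hypergeom_upper_tail(q)})
    if not rows:
        return []
    adj = stats.bh_adjust([r["p"] for r in rows])
    for r, a in zip(rows, adj):
        r["adj_p"] = float(a)
        r["significant"] = a <= adjusted_alpha
    return rows


def run_analysis(cfg: AnalysisConfig, outdir) -> Path:
    """Execute the configured analysis; returns the run directory.

    Writes, per combination: a reference-module table (module_id, gene,
    is_seed), a JSON summary with sizes/p-values/provenance, term-enrichment
    tables when an annotation map is configured, and focal-set statistics
    when a focal list is configured. Every output carries the config hash.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()

    def stage(name):
        logger.info("stage: %s", name)
        return name

    current = stage("load network")
    try:
        net = giant_component(simplify(load_edge_list(cfg.network)))
        seed_lists = {label: load_gene_list(path, source_label=label).restricted_to(net)
                      for label, path in cfg.seed_lists.items()}
        annotation = stats.read_gmt(cfg.annotation) if cfg.annotation else None
        focal_set = (FocalSet(core=load_gene_list(cfg.focal, "focal").genes & net.nodes,
                              label="focal") if cfg.focal else None)

        current = stage("partitioning")
        partitions = consensus.detect_communities(net, n_runs=cfg.n_runs,
                                                  base_seed=cfg.base_seed)

        summary = {"config_hash": chash, "config": asdict(cfg), "combinations": []}
        module_collections = []
        for combo in cfg.combinations:
            current = stage(f"combination {'+'.join(combo)}")
            seeds = combine_seed_lists([seed_lists[l] for l in combo])
            modules = consensus.reference_modules(
                net, seeds, alpha=cfg.alpha_module, partitions=partitions)
            module_collections.append(modules)
            tag = "+".join(combo)
            _write_module_table(modules, seeds, outdir / f"modules_{tag}.tsv", chash)
            entry = {
                "combination": combo,
                "n_seeds_on_network": len(seeds.genes),
                "n_reference_modules": len(modules),
                "modules": [{"size": m.size, "n_seeds": m.n_seeds,
                             "p_value": m.p_value,
                             "merged_from_runs": sorted({r for r, _ in m.merged_from})}
                            for m in modules],
            }
            if annotation is not None:
                current = stage(f"term enrichment {tag}")
                universe = set()
                for gs in annotation.values():
                    universe |= gs
                terms = []
                for i, m in enumerate(modules):
                    res = stats.term_enrichment(m.nodes & universe, annotation,
                                                universe, alpha=cfg.alpha_term)
                    frame = stats.results_frame(res)
                    frame.insert(0, "module", i)
                    terms.append(frame)
                if terms:
                    import pandas as pd

                    table = pd.concat(terms, ignore_index=True)
                    table.to_csv(outdir / f"terms_{tag}.tsv", sep="\t", index=False)
                    entry["n_significant_terms"] = int(table["significant"].sum())
            if focal_set is not None and focal_set.core:
                current = stage(f"focal statistics {tag}")
                hood = focal_mod.neighborhood_enrichment(net, focal_set, [seeds])
                dist = focal_mod.distance_null_test(
                    net, focal_mod.closed_neighborhood(net, focal_set.core),
                    seeds, n_resamples=cfg.n_resamples, mode="avg",
                    rng_seed=cfg.base_seed)
                entry["focal"] = {
                    "neighborhood_enrichment": hood.to_dict(orient="records"),
                    "distance_combined_p": dist.combined_p,
                }
            summary["combinations"].append(entry)

        if focal_set is not None and focal_set.core and module_collections:
            current = stage("focal frequency test")
            non_focal = net.nodes - focal_set.core
            freq = focal_mod.node_frequency_test(module_collections,
                                                 focal_set.core, non_focal)
            summary["focal_frequency_wilcoxon_p"] = freq.wilcoxon_p

        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise RuntimeError(f"analysis failed at stage {current!r}: {exc}") from exc
    return outdir


def _write_module_table(modules, seeds: SeedGeneList, path, chash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        fh.write("module_id\tgene\tis_seed\n")
        for i, m in enumerate(modules):
            for gene in sorted(m.nodes):
                fh.write(f"{i}\t{gene}\t{int(gene in seeds.genes)}\n")
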