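"""Synthetic data with known ground truth.

Every downstream stage of the pipeline — signature extraction, consensus
module detection, seed enrichment, term enrichment, proximity statistics —
is testable against data generated here, with no external downloads:

* planted-partition networks whose module structure a modularity-maximising
  partitioner can recover;
* seed-gene lists preferentially sampled from designated "disease" modules;
* case/control expression matrices with region-specific up/down-shifted
  genes over multiplicative lognormal noise;
* random term->gene annotation maps with one planted enriched term.

All generators are bit-reproducible from their ``rng_seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import PPINetwork, SeedGeneList
from .signatures import ExpressionMatrix

__all__ = [
    "PlantedNetworkSpec",
    "SeedPlantSpec",
    "ExpressionSimSpec",
    "generate_planted_network",
    "generate_seed_list",
    "generate_expression_matrix",
    "generate_annotation_map",
]

SEED_SOURCES = ("expression", "snp", "drug", "omim")


def _gene_names(n: int) -> list[str]:
    # module membership is deliberately NOT encoded in the name, so that no
    # string-ordering artifact can leak ground truth into rank-based stages
    return [f"G{i:04d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """Planted-partition (non-degree-corrected SBM) network parameters."""

    module_sizes: tuple
    p_in: float
    p_out: float
    rng_seed: int = 0

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.module_sizes)
        object.__setattr__(self, "module_sizes", sizes)
        if any(s <= 0 for s in sizes):
            raise ValueError("module sizes must be positive")
        if sum(sizes) < 2:
            raise ValueError("need at least 2 nodes in total")
        if not (0 <= self.p_in <= 1 and 0 <= self.p_out <= 1):
            raise ValueError("edge probabilities must lie in [0, 1]")
        if self.p_in <= self.p_out:
            warnings.warn("p_in <= p_out: planted modules will not be recoverable",
                          stacklevel=2)


def generate_planted_network(spec: PlantedNetworkSpec):
    """Sample a planted-partition network.

    Returns ``(network, partition)`` where ``partition`` maps gene symbol ->
    planted module index. Within-module pairs receive an edge with
    probability ``p_in``, between-module pairs with ``p_out``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = sum(spec.module_sizes)
    names = _gene_names(n)
    labels = np.repeat(np.arange(len(spec.module_sizes)), spec.module_sizes)
    g = nx.Graph()
    g.add_nodes_from(names)
    iu, ju = np.triu_indices(n, k=1)
    p = np.where(labels[iu] == labels[ju], spec.p_in, spec.p_out)
    keep = rng.random(p.size) < p
    g.add_edges_from((names[i], names[j]) for i, j in zip(iu[keep], ju[keep]))
    partition = {names[i]: int(labels[i]) for i in range(n)}
    net = PPINetwork(graph=g, provenance=f"planted-partition(seed={spec.rng_seed})")
    return net, partition


@dataclass(frozen=True)
class SeedPlantSpec:
    """Bernoulli seed-sampling parameters over a planted partition.

    Genes inside the designated disease modules become seeds with
    probability ``q_in``, all others with ``q_out``; emulates an evidence
    source (expression signature, SNP association, drug target, OMIM entry)
    that is concentrated in, but not confined to, disease-relevant modules.
    """

    source_label: str = "expression"
    disease_module_ids: frozenset = frozenset({0})
    q_in: float = 0.5
    q_out: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "disease_module_ids", frozenset(self.disease_module_ids))
        if self.source_label not in SEED_SOURCES:
            raise ValueError(f"source_label must be one of {SEED_SOURCES}")
        if not (0 <= self.q_out <= self.q_in <= 1):
            raise ValueError("require 0 <= q_out <= q_in <= 1")


def generate_seed_list(network: PPINetwork, partition, spec: SeedPlantSpec) -> SeedGeneList:
    """Sample a seed-gene list from a partitioned network."""
    if network.n_nodes == 0:
        raise ValueError("empty network")
    unknown = spec.disease_module_ids - set(partition.values())
    if unknown:
        raise ValueError(f"disease modules not present in partition: {sorted(unknown)}")
    rng = np.random.default_rng(spec.rng_seed)
    genes = set()
    for gene in sorted(network.nodes):
        q = spec.q_in if partition[gene] in spec.disease_module_ids else spec.q_out
        if rng.random() < q:
            genes.add(gene)
    return SeedGeneList(genes=genes, source_label=spec.source_label)


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Case/control expression simulation with region-specific effects.

    Emulates a multi-region brain expression study (a handful of cases and
    controls per region). Controls follow a per-gene lognormal baseline;
    case samples of a region have its ``up`` genes multiplied by
    ``2**log2_effect`` and its ``down`` genes by ``2**-log2_effect``.
    ``noise_sd`` is the per-measurement multiplicative noise SD on the log2
    scale.
    """

    n_genes: int = 1000
    regions: tuple = ("HIP", "PC")
    n_cases: int = 12
    n_controls: int = 12
    affected_genes: dict = field(default_factory=dict)
    log2_effect: float = 2.0
    noise_sd: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.log2_effect < 0:
            raise ValueError("log2_effect must be non-negative")
        if self.n_controls < 2:
            raise ValueError("need at least 2 controls per region")
        if self.n_cases < 1:
            raise ValueError("need at least 1 case per region")
        for region, (up, down) in self.affected_genes.items():
            if set(up) & set(down):
                raise ValueError(f"up/down sets overlap for region {region}")


def generate_expression_matrix(spec: ExpressionSimSpec) -> ExpressionMatrix:
    """Sample a genes x samples positive expression matrix plus sample metadata."""
    rng = np.random.default_rng(spec.rng_seed)
    genes = _gene_names(spec.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    # per-gene baseline shared by all samples: lognormal around ~100
    baseline = np.exp(rng.normal(np.log(100.0), 1.0, size=spec.n_genes))

    columns, meta_rows = [], []
    values = []
    for region in spec.regions:
        up, down = spec.affected_genes.get(region, (set(), set()))
        shift = np.zeros(spec.n_genes)
        shift[[gene_index[g] for g in up]] = spec.log2_effect
        shift[[gene_index[g] for g in down]] = -spec.log2_effect
        for group, count, eff in (("control", spec.n_controls, 0.0),
                                  ("case", spec.n_cases, 1.0)):
            for s in range(count):
                name = f"{region}_{group}_{s + 1}"
                noise = rng.normal(0.0, spec.noise_sd, size=spec.n_genes)
                values.append(baseline * np.exp2(eff * shift + noise))
                columns.append(name)
                meta_rows.append({"sample": name, "region": region, "group": group})
    frame = pd.DataFrame(np.column_stack(values), index=genes, columns=columns)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return ExpressionMatrix(values=frame, sample_meta=meta)


def generate_annotation_map(genes, n_terms: int, term_size_range=(5, 50),
                            planted_term=None, rng_seed: int = 0) -> dict[str, set]:
    """Random term->gene map, optionally with one planted term.

    ``planted_term`` is a ``(term_id, gene_set)`` pair inserted verbatim —
    typically an exact copy of a planted network module, so that term
    enrichment of that module must rank it first.
    """
    genes = sorted(set(genes))
    rng = np.random.default_rng(rng_seed)
    lo, hi = term_size_range
    if hi > len(genes):
        raise ValueError(f"term size {hi} exceeds universe of {len(genes)} genes")
    if not (1 <= lo <= hi):
        raise ValueError("invalid term_size_range")
    annotation: dict[str, set] = {}
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        annotation[f"T{t:04d}"] = {genes[i] for i in members}
    if planted_term is not None:
        term_id, members = planted_term
        members = set(members)
        if not members <= set(genes):
            raise ValueError("planted term genes outside universe")
        annotation[str(term_id)] = members
    return annotation
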