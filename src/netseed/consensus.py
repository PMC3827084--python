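"""Consensus reference modules from repeated stochastic partitioning.

A spinglass-style modularity heuristic is run many times on the giant
component; each run's modules are tested for seed-gene enrichment with an
upper-tail hypergeometric test (universe = network nodes); the enriched
modules from all runs are grouped by size (Sturges histogram bins) and
greedily merged within a group whenever the union (i) stays significantly
enriched and (ii) induces a connected subgraph. The surviving unions are
the "reference modules" — connected, significantly seed-enriched node sets
that summarise what the stochastic partitioner finds repeatedly.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np

from .network import PPINetwork, SeedGeneList
from .stats import HypergeomQuery, bh_adjust, hypergeom_upper_tail

logger = logging.getLogger(__name__)

__all__ = [
    "RunPartition",
    "EnrichedModule",
    "ReferenceModule",
    "spinglass_backend",
    "detect_communities",
    "enriched_modules",
    "sturges_size_groups",
    "merge_modules",
    "reference_modules",
]


@dataclass
class RunPartition:
    run_id: int
    modules: list  # list of frozensets partitioning the node set
    rng_seed: int


@dataclass
class EnrichedModule:
    run_id: int
    module_index: int
    nodes: frozenset
    n_seeds: int
    p_value: float


@dataclass
class ReferenceModule:
    nodes: frozenset
    edges: frozenset  # induced edges, as frozenset pairs
    n_seeds: int
    p_value: float
    merged_from: list  # (run_id, module_index) provenance
    size_group_id: int = -1

    @property
    def size(self) -> int:
        return len(self.nodes)


def spinglass_backend(graph: ig.Graph, seed: int) -> list[int]:
    """Default partitioner: igraph's spinglass Potts-model heuristic.

    python-igraph draws its random numbers from Python's ``random`` module,
    so seeding it makes each run reproducible. Backend parameters are left
    at igraph defaults.
    """
    random.seed(seed)
    return graph.community_spinglass().membership


def _to_igraph(net: PPINetwork):
    nodes = sorted(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in net.graph.edges]
    return ig.Graph(n=len(nodes), edges=edges), nodes


def detect_communities(net: PPINetwork, n_runs: int, base_seed: int,
                       backend=spinglass_backend) -> list[RunPartition]:
    """Run the stochastic partitioner ``n_runs`` times (run r seeded base_seed+r)."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    if not nx.is_connected(net.graph):
        raise ValueError("network must be connected (use the giant component)")
    graph, nodes = _to_igraph(net)
    partitions = []
    for r in range(n_runs):
        seed = base_seed + r
        membership = backend(graph, seed)
        modules: dict[int, set] = {}
        for v, m in zip(nodes, membership):
            modules.setdefault(m, set()).add(v)
        partitions.append(RunPartition(
            run_id=r,
            modules=[frozenset(modules[m]) for m in sorted(modules)],
            rng_seed=seed,
        ))
    return partitions


def enriched_modules(partition: RunPartition, seeds, alpha: float,
                     universe_size: int, adjust: str | None = None) -> list[EnrichedModule]:
    """Per-module upper-tail hypergeometric seed-enrichment tests.

    Universe N = network size, K = |seeds|, draws n = |module|, observed
    k = |module ∩ seeds|; modules with p <= alpha are kept. Singleton
    modules are excluded (the test is degenerate on one draw). The default
    applies the threshold to each test separately; ``adjust='bh'``
    BH-corrects across the run's modules before thresholding.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha={alpha} outside (0, 1)")
    if adjust not in (None, "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    seeds = set(seeds.genes) if isinstance(seeds, SeedGeneList) else set(seeds)
    K = len(seeds)
    tested = []
    for idx, module in enumerate(partition.modules):
        if len(module) < 2:
            logger.debug("run %d: skipping singleton module", partition.run_id)
            continue
        k = len(module & seeds)
        p = hypergeom_upper_tail(HypergeomQuery(N=universe_size, K=K, n=len(module), k=k))
        tested.append((idx, frozenset(module), k, p))
    if not tested:
        return []
    thresholded = [t[3] for t in tested]
    if adjust == "bh":
        thresholded = bh_adjust(thresholded)
    return [EnrichedModule(run_id=partition.run_id, module_index=idx,
                           nodes=nodes, n_seeds=k, p_value=p)
            for (idx, nodes, k, p), crit in zip(tested, thresholded)
            if crit <= alpha]


def sturges_size_groups(modules: list[EnrichedModule]) -> list[list[EnrichedModule]]:
    """Group enriched modules by size into Sturges histogram bins.

    ceil(log2(m)) + 1 equal-width, right-closed bins spanning
    [min size, max size], with the minimum included in the first bin —
    the classic histogram default. Modules in one bin form one group.
    """
    if not modules:
        raise ValueError("no modules to group")
    sizes = np.array([len(m.nodes) for m in modules])
    lo, hi = sizes.min(), sizes.max()
    if lo == hi:
        return [list(modules)]
    n_bins = int(np.ceil(np.log2(len(modules)))) + 1
    edges = np.linspace(lo, hi, n_bins + 1)
    # right-closed bins (lo, e1], (e1, e2], ...; lo itself joins the first bin
    idx = np.clip(np.searchsorted(edges, sizes, side="left") - 1, 0, n_bins - 1)
    groups: dict[int, list[EnrichedModule]] = {}
    for m, b in zip(modules, idx):
        groups.setdefault(int(b), []).append(m)
    return [groups[b] for b in sorted(groups)]


def _union_stats(nodes: frozenset, seeds: set, universe_size: int) -> tuple[int, float]:
    k = len(nodes & seeds)
    K = len(seeds)
    p = hypergeom_upper_tail(HypergeomQuery(N=universe_size, K=K, n=len(nodes), k=k))
    return k, p


def _greedy_merge(clusters: list[dict], net: PPINetwork, seeds: set,
                  alpha: float) -> list[dict]:
    """Greedy agglomeration of overlapping clusters.

    Repeatedly consider the overlapping pair with the largest Jaccard
    overlap; accept the union iff it is still significantly seed-enriched
    at ``alpha`` AND induces a connected subgraph. A rejected pair is never
    retried; disjoint clusters are never merged.
    """
    N = net.n_nodes
    clusters = [dict(c) for c in clusters]
    rejected: set[frozenset] = set()  # pairs of cluster node-sets that failed the test

    def jaccard(a, b):
        return len(a & b) / len(a | b)

    while True:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i]["nodes"], clusters[j]["nodes"]
                if not a & b or frozenset((a, b)) in rejected:
                    continue
                jac = jaccard(a, b)
                if best is None or jac > best[0]:
                    best = (jac, i, j)
        if best is None:
            break
        _, i, j = best
        a, b = clusters[i], clusters[j]
        union = frozenset(a["nodes"] | b["nodes"])
        _, p = _union_stats(union, seeds, N)
        if p <= alpha and nx.is_connected(net.graph.subgraph(union)):
            merged = {"nodes": union, "from": a["from"] + b["from"]}
            clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
            clusters.append(merged)
        else:
            rejected.add(frozenset((a["nodes"], b["nodes"])))
    return clusters


def merge_modules(group: list[EnrichedModule], net: PPINetwork, seeds,
                  alpha: float, size_group_id: int = -1) -> list[ReferenceModule]:
    """Merge one size group of enriched modules into reference modules.

    Greedy largest-Jaccard-first agglomeration; a union is accepted iff it
    remains significantly seed-enriched AND induces a connected subgraph (a
    reference module must be a connected node set). Reference-module
    nodes/edges are the union over all merged runs — the largest set of
    genes and interactions the different runs support.
    """
    seeds = set(seeds.genes) if isinstance(seeds, SeedGeneList) else set(seeds)
    N = net.n_nodes
    clusters = _greedy_merge(
        [{"nodes": m.nodes, "from": [(m.run_id, m.module_index)]} for m in group],
        net, seeds, alpha)
    out = []
    for c in clusters:
        nodes = c["nodes"]
        k, p = _union_stats(nodes, seeds, N)
        sub = net.graph.subgraph(nodes)
        if not nx.is_connected(sub):
            # a raw partition module can in principle be disconnected; keep
            # its significant connected pieces so the contract holds
            logger.warning("splitting a disconnected candidate of size %d", len(nodes))
            for comp in nx.connected_components(sub):
                comp = frozenset(comp)
                if len(comp) < 2:
                    continue
                kk, pp = _union_stats(comp, seeds, N)
                if pp <= alpha:
                    out.append(ReferenceModule(
                        nodes=comp,
                        edges=frozenset(frozenset(e) for e in net.graph.subgraph(comp).edges),
                        n_seeds=kk, p_value=pp, merged_from=list(c["from"]),
                        size_group_id=size_group_id))
            continue
        out.append(ReferenceModule(
            nodes=nodes,
            edges=frozenset(frozenset(e) for e in sub.edges),
            n_seeds=k, p_value=p, merged_from=list(c["from"]),
            size_group_id=size_group_id))
    out.sort(key=lambda m: (m.p_value, -m.size, sorted(m.nodes)))
    return out


def reference_modules(net: PPINetwork, seeds, n_runs: int = 100,
                      alpha: float = 0.05, base_seed: int = 0,
                      backend=spinglass_backend,
                      partitions: list[RunPartition] | None = None) -> list[ReferenceModule]:
    """Full consensus procedure: detect -> enrich -> group by size -> merge.

    ``partitions`` may supply precomputed run partitions (partitioning does
    not depend on the seed list, so the expensive stage can be shared across
    seed-list combinations). An empty seed list, or no enriched module in
    any run, yields an empty result.
    """
    seed_set = set(seeds.genes) if isinstance(seeds, SeedGeneList) else set(seeds)
    seed_set &= net.nodes
    if not seed_set:
        return []
    if partitions is None:
        partitions = detect_communities(net, n_runs=n_runs, base_seed=base_seed,
                                        backend=backend)
    enriched: list[EnrichedModule] = []
    for part in partitions:
        enriched.extend(enriched_modules(part, seed_set, alpha, net.n_nodes))
    if not enriched:
        return []
    per_group: list[ReferenceModule] = []
    for gid, group in enumerate(sturges_size_groups(enriched)):
        per_group.extend(merge_modules(group, net, seed_set, alpha, size_group_id=gid))
    # size bins are a pre-ordering heuristic for merging: the same underlying
    # community can straddle a bin boundary (e.g. found at sizes 29 and 30 in
    # different runs), so consolidate across groups with the same accept rule
    merged = _greedy_merge(
        [{"nodes": m.nodes, "from": list(m.merged_from), "gid": m.size_group_id}
         for m in per_group],
        net, seed_set, alpha)
    result: list[ReferenceModule] = []
    for c in merged:
        k, p = _union_stats(c["nodes"], seed_set, net.n_nodes)
        result.append(ReferenceModule(
            nodes=c["nodes"],
            edges=frozenset(frozenset(e) for e in net.graph.subgraph(c["nodes"]).edges),
            n_seeds=k, p_value=p,
            merged_from=sorted(set(c["from"])),
            size_group_id=c.get("gid", -1)))
    result.sort(key=lambda m: (m.p_value, -m.size, sorted(m.nodes)))
    return result
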