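"""Protein–protein interaction network scaffold.

Loads two-column edge lists of gene symbols, cleans them (self-loop and
duplicate removal), extracts the giant component that serves as the analysis
universe, and answers neighborhood and shortest-path queries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "SeedGeneList",
    "FocalSet",
    "load_edge_list",
    "load_gene_list",
    "simplify",
    "giant_component",
    "closed_neighborhood",
    "shortest_path_lengths",
    "write_edge_list",
]


@dataclass
class PPINetwork:
    """Simple undirected graph over gene symbols.

    ``graph`` is a networkx Graph whose nodes are upper-cased gene symbols.
    A freshly loaded network may still contain self-loops; ``simplify``
    removes them. Duplicate input edges (in either orientation) collapse on
    load because the edge set is unordered.
    """

    graph: nx.Graph
    provenance: str = ""

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set:
        return {frozenset((u, v)) if u != v else frozenset((u,)) for u, v in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class SeedGeneList:
    """A labeled set of seed genes from one evidence source."""

    genes: set
    source_label: str = "unknown"

    def __len__(self) -> int:
        return len(self.genes)

    def restricted_to(self, net: PPINetwork) -> "SeedGeneList":
        """Drop seed genes absent from the network, logging the count.

        The hypergeometric universe is the network node set, so seeds the
        network does not contain cannot participate in any test.
        """
        present = self.genes & net.nodes
        dropped = len(self.genes) - len(present)
        if dropped:
            logger.info("seed list %s: dropped %d/%d genes absent from network",
                        self.source_label, dropped, len(self.genes))
        return SeedGeneList(genes=present, source_label=self.source_label)


@dataclass
class FocalSet:
    """A focal gene set whose network relatedness to seeds is tested.

    The motivating example is the 9-gene AMP-activated protein kinase core
    (PRKAA1/2, PRKAB1/2, PRKAG1/2/3, ACACA, ACACB).
    """

    core: set
    label: str = "focal"


def _normalize(symbol: str) -> str:
    return symbol.strip().upper()


def load_edge_list(path, header: bool = False) -> PPINetwork:
    """Load a two-column TSV edge list into a raw network.

    Symbols are upper-cased; comment lines starting with '#' and blank lines
    are skipped; with ``header=True`` the first data line is discarded. The
    raw network may contain self-loops (removed later by ``simplify``).
    Lines with a column count other than two raise with the line number.
    """
    g = nx.Graph()
    raw_lines = 0
    with open(path) as fh:
        first_data = True
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if first_data and header:
                first_data = False
                continue
            first_data = False
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
            a, b = _normalize(parts[0]), _normalize(parts[1])
            if not a or not b:
                raise ValueError(f"{path}: line {lineno}: empty gene symbol")
            raw_lines += 1
            g.add_edge(a, b)
    if raw_lines == 0:
        logger.warning("edge list %s is empty", path)
    logger.info("loaded %s: %d raw interaction lines -> %d nodes, %d edges",
                path, raw_lines, g.number_of_nodes(), g.number_of_edges())
    return PPINetwork(graph=g, provenance=str(path))


def load_gene_list(path, source_label: str = "unknown") -> SeedGeneList:
    """Read a one-symbol-per-line gene list ('#' comments skipped)."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(_normalize(line))
    return SeedGeneList(genes=genes, source_label=source_label)


def simplify(net: PPINetwork) -> PPINetwork:
    """Remove self-loops; node set unchanged. Idempotent.

    Duplicate edges cannot survive loading (the unordered edge set collapses
    them), so loop removal is the only remaining cleaning step.
    """
    g = net.graph.copy()
    loops = list(nx.selfloop_edges(g))
    g.remove_edges_from(loops)
    if loops:
        logger.info("removed %d self-loops", len(loops))
    return PPINetwork(graph=g, provenance=net.provenance)


def giant_component(net: PPINetwork) -> PPINetwork:
    """The maximal connected component — the analysis universe.

    Ties between equal-size largest components are broken deterministically
    in favour of the component containing the lexicographically smallest
    gene symbol (a warning is emitted when a tie occurs).
    """
    if net.n_nodes == 0:
        raise ValueError("cannot take the giant component of an empty network")
    comps = sorted(nx.connected_components(net.graph),
                   key=lambda c: (-len(c), min(c)))
    if len(comps) > 1 and len(comps[0]) == len(comps[1]):
        logger.warning("giant component tie (size %d); choosing the component "
                       "with the smallest gene symbol", len(comps[0]))
    g = net.graph.subgraph(comps[0]).copy()
    return PPINetwork(graph=g, provenance=net.provenance)


def closed_neighborhood(net: PPINetwork, core) -> set:
    """``core`` together with every node adjacent to it.

    The "core nodes + direct neighbors" construction used to extend a focal
    gene set (e.g. the AMPK subunits) to its immediate interaction partners.
    """
    core = set(core)
    missing = core - net.nodes
    if missing:
        raise KeyError(f"core genes absent from network: {sorted(missing)}")
    out = set(core)
    for c in core:
        out.update(net.graph.neighbors(c))
    return out


def shortest_path_lengths(net: PPINetwork, sources, targets) -> pd.DataFrame:
    """Unweighted shortest-path hop counts, sources x targets.

    BFS from each source, restricted to the requested targets. The network
    is expected to be connected (the giant component); an unreachable pair
    therefore indicates a contract violation and raises.
    """
    sources, targets = sorted(set(sources)), sorted(set(targets))
    missing = (set(sources) | set(targets)) - net.nodes
    if missing:
        raise KeyError(f"query genes absent from network: {sorted(missing)}")
    mat = np.empty((len(sources), len(targets)), dtype=float)
    for i, s in enumerate(sources):
        dist = nx.single_source_shortest_path_length(net.graph, s)
        for j, t in enumerate(targets):
            if t not in dist:
                raise AssertionError(f"{t} unreachable from {s} on a supposedly connected network")
            mat[i, j] = dist[t]
    return pd.DataFrame(mat, index=sources, columns=targets)


def write_edge_list(net: PPINetwork, path) -> None:
    """Write the network as a two-column TSV edge list (sorted, deterministic)."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{u}\t{v}\n")
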