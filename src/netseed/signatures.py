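"""Rank-based expression signatures and the signature-distance sample map.

The signature procedure is ratio -> rank -> rank-sum -> re-rank:

1. divide each case profile by the mean of its region's controls,
2. rank every case profile separately (rank 1 = most over-expressed),
3. sum ranks per region and re-rank genes by the rank sum,
4. keep the top-k as the "up" list and the bottom-k as the "down" list.

Because only per-sample ranks enter, the pipeline is invariant to any
positive per-sample rescaling. The sample map connects the most similar
per-sample signatures (smallest pairwise distances), which on real
multi-region brain data clusters samples by tissue of origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ExpressionMatrix",
    "Signature",
    "differential_profiles",
    "rank_profiles",
    "region_signature",
    "per_sample_signatures",
    "signature_distance",
    "signature_map",
    "collapse_probes",
    "read_expression",
    "write_signature",
]

DEFAULT_K = 125


@dataclass
class ExpressionMatrix:
    """Positive genes x samples matrix plus per-sample (region, group) labels."""

    values: pd.DataFrame
    sample_meta: pd.DataFrame  # index: sample; columns: region, group in {case, control}

    def __post_init__(self) -> None:
        if not set(self.values.columns) <= set(self.sample_meta.index):
            raise ValueError("samples in the matrix missing from sample_meta")
        bad = set(self.sample_meta["group"]) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def regions(self) -> list[str]:
        return sorted(self.sample_meta["region"].unique())

    def samples(self, region: str, group: str) -> list[str]:
        m = self.sample_meta
        sel = m.index[(m["region"] == region) & (m["group"] == group)]
        return [s for s in self.values.columns if s in set(sel)]


@dataclass
class Signature:
    """Ordered top-k "up" and bottom-k "down" gene lists for one region/sample."""

    region: str
    up: tuple
    down: tuple

    def __post_init__(self) -> None:
        self.up, self.down = tuple(self.up), tuple(self.down)
        if len(self.up) != len(self.down):
            raise ValueError("up and down lists must have equal length k")
        if set(self.up) & set(self.down):
            raise ValueError("up and down lists overlap")

    @property
    def k(self) -> int:
        return len(self.up)


def differential_profiles(m: ExpressionMatrix, region: str) -> pd.DataFrame:
    """Per-case ratio profiles: case value / mean(control values) per gene."""
    cases = m.samples(region, "case")
    controls = m.samples(region, "control")
    if region not in m.regions:
        raise ValueError(f"unknown region {region!r}")
    if not cases or len(controls) < 2:
        raise ValueError(f"region {region!r} needs >=1 case and >=2 controls")
    ctrl_mean = m.values[controls].mean(axis=1)
    bad = ctrl_mean[ctrl_mean <= 0]
    if len(bad):
        raise ValueError(f"non-positive control mean for genes {list(bad.index[:5])}")
    return m.values[cases].div(ctrl_mean, axis=0)


def rank_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Rank each profile from most to least expressed (rank 1 = largest).

    Ties receive the average of the tied rank positions.
    """
    if profiles.shape[1] == 0:
        raise ValueError("no profiles to rank")
    if profiles.isna().any().any():
        raise ValueError("NaN in expression profile")
    ranked = profiles.apply(lambda col: rankdata(-col.to_numpy(), method="average"))
    return pd.DataFrame(ranked.to_numpy(), index=profiles.index, columns=profiles.columns)


def region_signature(rank_vectors: pd.DataFrame, k: int = DEFAULT_K,
                     region: str = "") -> Signature:
    """Sum per-sample ranks, re-rank by the sum, keep top-k and bottom-k.

    Small rank sums mean consistently over-expressed genes ("up"); large
    rank sums mean consistently under-expressed genes ("down"). Within each
    list genes are ordered by rank sum (extreme first), gene name breaking
    ties deterministically.
    """
    n_genes = rank_vectors.shape[0]
    if 2 * k > n_genes:
        raise ValueError(f"2k={2 * k} exceeds the {n_genes} available genes")
    if rank_vectors.shape[1] == 0:
        raise ValueError("need at least one rank vector")
    sums = rank_vectors.sum(axis=1)
    # stable sort over a name-sorted index: rank-sum ties break by gene name
    order = sums.loc[sorted(sums.index)].sort_values(kind="mergesort").index
    up = tuple(order[:k])
    down = tuple(order[-k:][::-1])  # most under-expressed first
    return Signature(region=region, up=up, down=down)


def per_sample_signatures(m: ExpressionMatrix, k: int = DEFAULT_K) -> dict[str, Signature]:
    """One signature per case sample (top-k/bottom-k of its own ranked profile).

    These per-sample signatures are the nodes of the sample map.
    """
    out: dict[str, Signature] = {}
    for region in m.regions:
        profiles = differential_profiles(m, region)
        ranks = rank_profiles(profiles)
        for sample in ranks.columns:
            out[sample] = region_signature(ranks[[sample]], k=k, region=region)
    return out


def signature_distance(a: Signature, b: Signature) -> float:
    """Signed-overlap distance in [0, 1].

    1 - (|up overlap| + |down overlap|) / 2k: 0 for identical signatures,
    1 for signatures sharing no gene in matching direction. Symmetric.
    """
    if a.k != b.k:
        raise ValueError(f"signature half-lengths differ: {a.k} != {b.k}")
    shared = len(set(a.up) & set(b.up)) + len(set(a.down) & set(b.down))
    return 1.0 - shared / (2 * a.k)


def signature_map(signatures: dict[str, Signature], edge_fraction: float = 0.2,
                  metric=signature_distance) -> nx.Graph:
    """Graph over samples keeping only the closest signature pairs as edges.

    Edges are the ``floor(edge_fraction * C(n, 2))`` sample pairs with the
    smallest distances; ties at the cutoff are broken by lexicographic pair
    order. Each retained edge stores its distance.
    """
    names = sorted(signatures)
    n = len(names)
    if n < 2:
        raise ValueError("need at least 2 signatures to build a map")
    if not 0 < edge_fraction <= 1:
        raise ValueError("edge_fraction must lie in (0, 1]")
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            pairs.append((metric(signatures[names[i]], signatures[names[j]]),
                          names[i], names[j]))
    pairs.sort()
    n_edges = int(np.floor(edge_fraction * len(pairs)))
    g = nx.Graph()
    g.add_nodes_from(names)
    for d, u, v in pairs[:n_edges]:
        g.add_edge(u, v, distance=d)
    return g


def collapse_probes(values: pd.DataFrame, probe_to_gene: dict) -> pd.DataFrame:
    """Optional many-to-one probe -> gene collapse keeping the max-mean probe."""
    mapped = values.loc[[p for p in values.index if p in probe_to_gene]].copy()
    mapped["__gene"] = [probe_to_gene[p] for p in mapped.index]
    means = mapped.drop(columns="__gene").mean(axis=1)
    best = (pd.DataFrame({"gene": mapped["__gene"], "mean": means})
            .sort_values(["gene", "mean"], ascending=[True, False])
            .drop_duplicates("gene"))
    out = values.loc[best.index]
    out.index = best["gene"].to_numpy()
    return out.sort_index()


def read_expression(matrix_path, meta_path) -> ExpressionMatrix:
    """Read a TSV matrix (genes x samples) and its sample-annotation sidecar."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ExpressionMatrix(values=values, sample_meta=meta)


def write_expression(m: ExpressionMatrix, matrix_path, meta_path) -> None:
    m.values.to_csv(matrix_path, sep="\t")
    m.sample_meta.to_csv(meta_path, sep="\t")


def write_signature(sig: Signature, path) -> None:
    """Write a signature as two-column TSV (gene, direction)."""
    with open(path, "w") as fh:
        for gene in sig.up:
            fh.write(f"{gene}\tup\n")
        for gene in sig.down:
            fh.write(f"{gene}\tdown\n")
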