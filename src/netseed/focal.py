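"""Relatedness of a focal gene set to seed genes on the network.

Three analyses, designed for a focal set such as the 9-gene AMP-activated
protein kinase core:

1. frequency of focal vs non-focal nodes across collections of reference
   modules (exact Wilcoxon rank-sum, Shapiro–Wilk reported as diagnostic);
2. hypergeometric seed enrichment of the focal closed neighborhood
   ("core + direct neighbors"), BH-adjusted across seed lists;
3. shortest-path distances from the focal nodes to the seeds compared
   against many random same-size node subsets, each comparison giving a
   one-sided Wilcoxon p-value, the per-resample p-values combined through
   the uniform-sum (Irwin–Hall) null: under H0 each p is Uniform(0,1), so
   their sum follows the Irwin–Hall distribution, which converges to
   N(n/2, n/12); systematically small p-values push the sum into the lower
   tail.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import mpmath
import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import mannwhitneyu, rankdata, shapiro

from .network import FocalSet, PPINetwork, SeedGeneList, closed_neighborhood
from .stats import HypergeomQuery, bh_adjust, hypergeom_upper_tail

logger = logging.getLogger(__name__)

__all__ = [
    "FrequencyTestResult",
    "DistanceNullResult",
    "irwin_hall_cdf",
    "combine_pvalues_uniform_sum",
    "node_frequency_test",
    "neighborhood_enrichment",
    "distance_null_test",
    "signed_rank_less_p",
]


# ---------------------------------------------------------------------------
# uniform-sum (Irwin–Hall) machinery


def irwin_hall_cdf(x: float, n: int) -> float:
    """CDF of the sum of ``n`` independent Uniform(0,1) variables.

    F(x) = (1/n!) * sum_{k=0}^{floor(x)} (-1)^k C(n,k) (x-k)_+^n
    for x in [0, n]; 0 below and 1 above the support. The alternating sum
    cancels catastrophically in floating point, so terms are accumulated in
    arbitrary precision sized to the worst-case term magnitude (exact for
    small n, a few hundred digits at n ~ 1000).
    """
    if n < 1:
        raise ValueError("n must be a positive integer")
    x = float(x)
    if x <= 0.0:
        return 0.0
    if x >= n:
        return 1.0
    # worst-case term ~ C(n, n/2) x^n / n!; give log10 of that plus margin
    log10_max = (n * math.log10(max(x, 1.0))
                 + (math.lgamma(n + 1) - 2 * math.lgamma(n / 2 + 1)) / math.log(10)
                 - math.lgamma(n + 1) / math.log(10))
    dps = max(30, int(log10_max) + 30)
    with mpmath.workdps(dps):
        xm = mpmath.mpf(x)
        total = mpmath.mpf(0)
        for k in range(int(math.floor(x)) + 1):
            term = mpmath.binomial(n, k) * (xm - k) ** n
            total += term if k % 2 == 0 else -term
        val = total / mpmath.factorial(n)
        return min(1.0, max(0.0, float(val)))


def combine_pvalues_uniform_sum(p_values, method: str = "normal") -> float:
    """Combine p-values through the uniform-sum null; returns the lower tail.

    Under H0 the p-values are i.i.d. Uniform(0,1) and their sum S has mean
    n/2 and variance n/12. ``method='normal'`` applies the central-limit
    approximation Phi((S - n/2) / sqrt(n/12)); ``method='exact'`` evaluates
    the Irwin–Hall CDF at S. Small combined values indicate the individual
    p-values are collectively smaller than chance.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    s = float(p.sum())
    if method == "normal":
        return float(ndtr((s - n / 2.0) / math.sqrt(n / 12.0)))
    if method == "exact":
        return irwin_hall_cdf(s, n)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# analysis 1: node frequency in reference-module collections


@dataclass
class FrequencyTestResult:
    focal_counts: pd.Series
    non_focal_counts: pd.Series
    shapiro_p_focal: float
    shapiro_p_non_focal: float
    wilcoxon_p: float


def node_frequency_test(collections, focal, non_focal) -> FrequencyTestResult:
    """Compare how often focal vs non-focal nodes occur in reference modules.

    ``collections`` is a list of reference-module collections (e.g., one per
    analysis configuration); a node's count is the number of collections in
    which at least one reference module contains it. The one-sided exact
    Wilcoxon rank-sum tests whether focal counts are higher. Shapiro–Wilk
    p-values for both count distributions are reported as diagnostics only;
    the non-parametric test is always used.
    """
    focal, non_focal = set(focal), set(non_focal)
    if not collections:
        raise ValueError("no reference-module collections")
    if focal & non_focal:
        raise ValueError("focal and non-focal sets overlap")
    if len(focal) < 2:
        raise ValueError("need at least 2 focal nodes for a rank test")

    def count(node):
        c = 0
        for coll in collections:
            member_sets = [m.nodes if hasattr(m, "nodes") else set(m) for m in coll]
            if any(node in s for s in member_sets):
                c += 1
        return c

    fc = pd.Series({v: count(v) for v in sorted(focal)}, dtype=int)
    nc = pd.Series({v: count(v) for v in sorted(non_focal)}, dtype=int)

    def _shapiro(vals):
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 3 or np.ptp(vals) == 0:
            return float("nan")
        return float(shapiro(vals).pvalue)

    return FrequencyTestResult(
        focal_counts=fc, non_focal_counts=nc,
        shapiro_p_focal=_shapiro(fc), shapiro_p_non_focal=_shapiro(nc),
        wilcoxon_p=rank_sum_greater_p(fc.to_numpy(), nc.to_numpy()),
    )


def rank_sum_greater_p(x, y, max_exact: int = 50000) -> float:
    """One-sided Wilcoxon rank-sum p that ``x`` stochastically exceeds ``y``.

    Exact by full enumeration of group assignments (midranks handle ties,
    conditioning on the observed values) whenever C(n1+n2, n1) is small
    enough; otherwise the tie-corrected normal approximation.
    """
    from itertools import combinations

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n = len(x), len(x) + len(y)
    ranks = rankdata(np.concatenate([x, y]))
    w_obs = ranks[:n1].sum()
    if math.comb(n, n1) <= max_exact:
        hits = total = 0
        for combo in combinations(range(n), n1):
            total += 1
            hits += ranks[list(combo)].sum() >= w_obs - 1e-9
        return hits / total
    return float(mannwhitneyu(x, y, alternative="greater",
                              method="asymptotic").pvalue)


# ---------------------------------------------------------------------------
# analysis 2: seed enrichment of the focal closed neighborhood


def neighborhood_enrichment(net: PPINetwork, focal_core: FocalSet,
                            seed_lists, include_union: bool = True) -> pd.DataFrame:
    """Seed enrichment of the focal core plus its direct neighbors.

    One hypergeometric upper-tail test per seed list (universe = network
    nodes) and one for their union; BH adjustment across all tested rows.
    Seeds absent from the network are dropped first.
    """
    hood = closed_neighborhood(net, focal_core.core)
    N, n = net.n_nodes, len(hood)
    rows = []
    union: set = set()
    for sl in seed_lists:
        sl = sl.restricted_to(net)
        union |= sl.genes
        k = len(hood & sl.genes)
        p = hypergeom_upper_tail(HypergeomQuery(N=N, K=len(sl.genes), n=n, k=k))
        rows.append({"seed_list": sl.source_label, "K": len(sl.genes),
                     "n": n, "k": k, "p": p})
    if include_union and len(seed_lists) > 1:
        k = len(hood & union)
        p = hypergeom_upper_tail(HypergeomQuery(N=N, K=len(union), n=n, k=k))
        rows.append({"seed_list": "union", "K": len(union), "n": n, "k": k, "p": p})
    frame = pd.DataFrame(rows)
    frame["adj_p"] = bh_adjust(frame["p"].to_numpy())
    return frame


# ---------------------------------------------------------------------------
# analysis 3: shortest-path distance null


@dataclass
class DistanceNullResult:
    mode: str
    focal_statistics: np.ndarray
    resample_p_values: np.ndarray
    combined_p: float
    rng_seed: int
    wilcoxon_flavor: str = "signed-rank"


def _distance_matrix(net: PPINetwork, seeds: list) -> tuple[dict, np.ndarray]:
    """BFS from every seed; returns node->row-index map and |nodes| x |seeds| hops."""
    import networkx as nx

    nodes = sorted(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    mat = np.empty((len(nodes), len(seeds)), dtype=float)
    for j, s in enumerate(seeds):
        dist = nx.single_source_shortest_path_length(net.graph, s)
        for v, d in dist.items():
            mat[index[v], j] = d
    return index, mat


def _statistic(rows: np.ndarray, mode: str) -> np.ndarray:
    if mode == "avg":
        return rows.mean(axis=1)
    if mode == "all":
        return rows.ravel()
    raise ValueError(f"unknown mode {mode!r}")


def signed_rank_less_p(diff: np.ndarray, exact_limit: int = 25) -> float:
    """P(focal < other): lower-tail Wilcoxon signed-rank p for paired differences.

    Zero differences are dropped (the classic Wilcoxon convention); an
    all-zero vector carries no evidence either way and scores 0.5. The
    exact null distribution of W+ (dynamic programming over rank subset
    sums) is used when there are no ties among |differences| and at most
    ``exact_limit`` non-zero pairs; otherwise the normal approximation with
    tie-corrected variance and continuity correction — the same convention
    R's wilcox.test follows.
    """
    d = np.asarray(diff, dtype=float)
    d = d[d != 0]
    m = d.size
    if m == 0:
        return 0.5
    absd = np.abs(d)
    r = rankdata(absd)
    w = float(r[d > 0].sum())
    has_ties = np.unique(absd).size < m
    if not has_ties and m <= exact_limit:
        total = m * (m + 1) // 2
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for rank in range(1, m + 1):
            counts[rank:] += counts[:-rank].copy()
        return float(counts[: int(w) + 1].sum() / 2.0**m)
    mu = m * (m + 1) / 4.0
    tie_sizes = np.unique(absd, return_counts=True)[1]
    var = m * (m + 1) * (2 * m + 1) / 24.0 - float(((tie_sizes**3 - tie_sizes).sum())) / 48.0
    if var <= 0:
        return 0.5
    return float(ndtr((w - mu + 0.5) / math.sqrt(var)))


def _one_sided_wilcoxon(focal_stat: np.ndarray, other_stat: np.ndarray) -> tuple[float, str]:
    """One-sided test that the focal statistics are smaller.

    Vectors of equal length are compared pairwise with the signed-rank test;
    unequal lengths fall back to the rank-sum test.
    """
    if focal_stat.shape == other_stat.shape:
        return signed_rank_less_p(focal_stat - other_stat), "signed-rank"
    res = mannwhitneyu(focal_stat, other_stat, alternative="less")
    return float(res.pvalue), "rank-sum"


def distance_null_test(net: PPINetwork, focal_nodes, seeds,
                       n_resamples: int = 1000, mode: str = "avg",
                       rng_seed: int = 0,
                       combine_method: str = "normal") -> DistanceNullResult:
    """Are focal nodes closer to the seeds than random node subsets are?

    The focal statistic vector holds, in ``mode='avg'``, each focal node's
    mean shortest-path distance to the seeds (one entry per focal node); in
    ``mode='all'`` every focal-by-seed distance. For each of ``n_resamples``
    random subsets of non-seed, non-focal nodes of matching size, the
    matched statistic vector is computed and compared with a one-sided
    Wilcoxon test (focal shorter); the resulting p-values are combined with
    the uniform-sum null. Sampling is without replacement within a subset,
    independent across subsets, and fully determined by ``rng_seed``.
    """
    focal_nodes = sorted(set(focal_nodes))
    seed_set = set(seeds.genes) if isinstance(seeds, SeedGeneList) else set(seeds)
    seed_set = sorted(seed_set & net.nodes)
    if not seed_set:
        raise ValueError("no seed genes on the network")
    missing = set(focal_nodes) - net.nodes
    if missing:
        raise KeyError(f"focal nodes absent from network: {sorted(missing)}")
    pool = sorted(net.nodes - set(seed_set) - set(focal_nodes))
    if len(pool) < len(focal_nodes):
        raise ValueError(f"eligible pool of {len(pool)} nodes is smaller than "
                         f"the focal set ({len(focal_nodes)})")

    index, dmat = _distance_matrix(net, seed_set)
    focal_rows = dmat[[index[v] for v in focal_nodes]]
    focal_stat = _statistic(focal_rows, mode)

    rng = np.random.default_rng(rng_seed)
    pool_idx = np.array([index[v] for v in pool])
    pvals = np.empty(n_resamples)
    flavor = "signed-rank"
    for r in range(n_resamples):
        pick = rng.choice(pool_idx, size=len(focal_nodes), replace=False)
        other_stat = _statistic(dmat[pick], mode)
        pvals[r], flavor = _one_sided_wilcoxon(focal_stat, other_stat)
    combined = combine_pvalues_uniform_sum(pvals, method=combine_method)
    return DistanceNullResult(mode=mode, focal_statistics=focal_stat,
                              resample_p_values=pvals, combined_p=combined,
                              rng_seed=rng_seed, wilcoxon_flavor=flavor)
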