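"""Core enrichment statistics.

Upper-tail hypergeometric tests, Benjamini–Hochberg adjustment, and generic
term enrichment of a gene set against a GMT-style annotation map. These
kernels back both the per-run module enrichment of the consensus procedure
and the functional characterisation of reference modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "HypergeomQuery",
    "TermEnrichmentResult",
    "hypergeom_upper_tail",
    "bh_adjust",
    "term_enrichment",
    "read_gmt",
    "write_gmt",
]


@dataclass(frozen=True)
class HypergeomQuery:
    """Parameters of one hypergeometric enrichment test.

    N: universe size; K: successes in the universe; n: draws (query size);
    k: observed successes among the draws.
    """

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"invalid universe: N={self.N}, K={self.K}, n={self.n}")
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError(f"k={self.k} outside [0, min(n={self.n}, K={self.K})]")


def hypergeom_upper_tail(q: HypergeomQuery) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    The probability of drawing at least ``k`` annotated genes when sampling
    ``n`` genes without replacement from a universe of ``N`` genes of which
    ``K`` are annotated. Returns a value in (0, 1]; ``k = 0`` gives exactly 1.
    """
    if q.k == 0:
        return 1.0
    # survival function at k-1 == P(X >= k); scipy evaluates the tail stably
    return float(hypergeom.sf(q.k - 1, q.N, q.K, q.n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class TermEnrichmentResult:
    term: str
    overlap: frozenset
    p_value: float
    adjusted_p: float
    query: HypergeomQuery
    significant: bool = field(default=False)


def term_enrichment(genes, annotation, universe, alpha: float = 0.001) -> list[TermEnrichmentResult]:
    """Hypergeometric term enrichment of ``genes`` against ``annotation``.

    Parameters
    ----------
    genes : iterable of str
        Query gene set; must be a subset of ``universe``.
    annotation : mapping term -> iterable of genes
        GMT-style term-to-gene map. Term genes outside the universe are
        ignored (K counts only annotated genes inside the universe).
    universe : iterable of str
        Background gene set (for module characterisation this is typically
        the set of annotated genes; for module seed tests the network nodes).
    alpha : float
        Raw p-value threshold used to flag significant terms (default 0.001).

    Returns results sorted by raw p-value (ties broken by term id), with
    BH-adjusted p-values computed across all tested terms.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    genes = set(genes)
    if not genes <= universe:
        missing = sorted(genes - universe)[:5]
        raise ValueError(f"query genes outside universe, e.g. {missing}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha={alpha} outside (0, 1)")

    N, n = len(universe), len(genes)
    rows = []
    for term in sorted(annotation):
        term_genes = set(annotation[term]) & universe
        overlap = term_genes & genes
        q = HypergeomQuery(N=N, K=len(term_genes), n=n, k=len(overlap))
        rows.append((term, overlap, q, hypergeom_upper_tail(q)))
    if not rows:
        return []
    adj = bh_adjust([r[3] for r in rows])
    results = [
        TermEnrichmentResult(term=t, overlap=frozenset(o), p_value=p,
                             adjusted_p=a, query=q, significant=p <= alpha)
        for (t, o, q, p), a in zip(rows, adj)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def results_frame(results: list[TermEnrichmentResult]) -> pd.DataFrame:
    """Tabulate term-enrichment results as (term, k, K, n, N, p, adj_p, significant)."""
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "k": [r.query.k for r in results],
            "K": [r.query.K for r in results],
            "n": [r.query.n for r in results],
            "N": [r.query.N for r in results],
            "p": [r.p_value for r in results],
            "adj_p": [r.adjusted_p for r in results],
            "significant": [r.significant for r in results],
        }
    )


def read_gmt(path) -> dict[str, set]:
    """Read a GMT file (term, description, then one gene per column)."""
    annotation: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed GMT line: {line!r}")
            annotation[parts[0]] = set(g for g in parts[2:] if g)
    return annotation


def write_gmt(annotation, path, descriptions=None) -> None:
    """Write a term -> gene-set map as GMT."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for term in sorted(annotation):
            desc = descriptions.get(term, "na")
            genes = "\t".join(sorted(annotation[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")
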