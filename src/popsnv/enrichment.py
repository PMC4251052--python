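"""Hypergeometric term enrichment with Benjamini–Hochberg FDR control.

For a query of n genes drawn from a universe of N, a term with K member
genes of which k appear in the query is scored by the upper-tail
hypergeometric probability P[X ≥ k]. Terms with fewer than ``min_genes``
query hits are excluded *before* testing, so the BH family is exactly
the set of terms actually tested. Only enrichment (upper tail) is
scored; no depletion test is offered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class TermCatalog:
    """Term → member-gene sets over a gene universe."""

    terms: Dict[str, Set[str]]
    term_names: Dict[str, str] = field(default_factory=dict)
    universe: Optional[Set[str]] = None

    def __post_init__(self):
        if self.universe is None:
            self.universe = set().union(*self.terms.values()) if self.terms else set()
        for tid, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {tid} has no member genes")
            if not genes <= self.universe:
                raise ValueError(f"term {tid} has genes outside the universe")

    @classmethod
    def from_table(cls, df: pd.DataFrame, universe: Optional[Set[str]] = None) -> "TermCatalog":
        """Build from a (term_id, term_name, gene_symbol) association table."""
        terms: Dict[str, Set[str]] = {}
        names: Dict[str, str] = {}
        for row in df.itertuples(index=False):
            terms.setdefault(row.term_id, set()).add(row.gene_symbol)
            names[row.term_id] = row.term_name
        return cls(terms=terms, term_names=names, universe=universe)

    def __len__(self) -> int:
        return len(self.terms)


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P[X ≥ k], X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(K, n, N) < 0:
        raise ValueError(f"infeasible counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def category_percent(k: int, K: int) -> float:
    """Percent of a term's K member genes present in the query."""
    if K < 1:
        raise ValueError("term size must be >= 1")
    return 100.0 * k / K


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    percent_of_category: float
    p_raw: float
    p_adjusted: float
    rank: int = 0


def enrich(
    query_genes: Iterable[str],
    catalog: TermCatalog,
    min_genes: int = 1,
) -> List[EnrichmentResult]:
    """Score every catalog term against a gene query.

    Query genes outside the universe are dropped (count logged via the
    returned results' shared ``n``); terms with fewer than ``min_genes``
    query hits are not tested at all, and BH adjustment runs over the
    tested terms only. Results are sorted by adjusted then raw p-value.
    """
    query = set(query_genes)
    mapped = query & catalog.universe
    if not mapped:
        raise ValueError("no query genes map into the catalog universe")
    n, N = len(mapped), len(catalog.universe)
    rows = []
    for tid in sorted(catalog.terms):
        genes = catalog.terms[tid]
        k = len(mapped & genes)
        if k < min_genes:
            continue
        K = len(genes)
        rows.append((tid, k, K, hypergeometric_p(k, K, n, N)))
    if not rows:
        return []
    adjusted = bh_adjust([r[3] for r in rows])
    results = [
        EnrichmentResult(
            term_id=tid,
            term_name=catalog.term_names.get(tid, tid),
            k=k,
            K=K,
            n=n,
            N=N,
            percent_of_category=category_percent(k, K),
            p_raw=p,
            p_adjusted=float(q),
        )
        for (tid, k, K, p), q in zip(rows, adjusted)
    ]
    results.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.term_id))
    for i, r in enumerate(results, start=1):
        r.rank = i
    return results


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Report table with the standard column set."""
    return pd.DataFrame(
        {
            "rank": [r.rank for r in results],
            "term_id": [r.term_id for r in results],
            "term_name": [r.term_name for r in results],
            "gene_count": [r.k for r in results],
            "percent_of_category": [r.percent_of_category for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
        }
    )
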