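"""Functional-term enrichment among TE-adjacent genes.

A plain one-sided (upper-tail) hypergeometric test per term with
Benjamini-Hochberg FDR control: exact, auditable, and independent of
any ontology service. The term table is taken as a flat gene -> term
mapping; no GO DAG propagation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import InvalidArgumentError


@dataclass
class TermMapping:
    term_id: str
    term_name: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise InvalidArgumentError(f"term {self.term_id} has no genes")


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int   # query genes carrying the term
    K: int   # background genes carrying the term
    n: int   # query size
    N: int   # background size
    p: float  # upper-tail hypergeometric probability P(X >= k)
    q: float  # BH-adjusted p


def load_term_table(path) -> list[TermMapping]:
    """Read a term-mapping TSV with columns term_id, term_name, gene_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"term_id", "term_name", "gene_id"}
    if not required <= set(df.columns):
        raise InvalidArgumentError(f"term table must have columns {sorted(required)}")
    out = []
    for (term_id, term_name), grp in df.groupby(["term_id", "term_name"], sort=True):
        out.append(TermMapping(term_id, term_name, frozenset(grp["gene_id"])))
    return out


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in input order."""
    pvals = np.asarray(list(pvalues), dtype=float)
    if pvals.size == 0:
        return []
    if np.any((pvals < 0) | (pvals > 1) | ~np.isfinite(pvals)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    return list(multipletests(pvals, method="fdr_bh")[1])


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    query: Iterable[str],
    background: Iterable[str],
    terms: Sequence[TermMapping],
    min_term: int = 5,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of each term in the query set.

    Terms are restricted to the background universe; terms covering
    fewer than ``min_term`` background genes are skipped. Results carry
    BH q-values over the tested terms and are sorted by (q, p, term_id).
    """
    query = set(query)
    background = set(background)
    strays = query - background
    if strays:
        raise InvalidArgumentError(
            f"query genes missing from background: {', '.join(sorted(strays)[:10])}"
        )
    N, n = len(background), len(query)
    tested = []
    for term in terms:
        term_bg = term.genes & background
        K = len(term_bg)
        if K < min_term:
            continue
        k = len(term_bg & query)
        tested.append((term, k, K, hypergeom_pvalue(k, K, n, N)))
    qvals = bh_adjust([p for _, _, _, p in tested])
    results = [
        EnrichmentResult(term.term_id, term.term_name, k, K, n, N, p, q)
        for (term, k, K, p), q in zip(tested, qvals)
    ]
    results.sort(key=lambda r: (r.q, r.p, r.term_id))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id, "term_name": r.term_name,
                "k": r.k, "K": r.K, "n": r.n, "N": r.N, "p": r.p, "q": r.q,
            }
            for r in results
        ],
        columns=["term_id", "term_name", "k", "K", "n", "N", "p", "q"],
    )
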