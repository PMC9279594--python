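"""Overrepresentation analysis of gene lists against annotation sets.

Given a query list (e.g. genes consistently up-regulated across a culture's
lifespan), a background list, and a collection of annotation terms (GO-style
gene sets supplied by the user), each term is tested for overrepresentation
with the one-sided Fisher's exact (hypergeometric upper-tail) test, fold
enrichment is reported as (k/n)/(K/N), and p-values are adjusted across
terms with the Benjamini–Hochberg procedure.

Terms are treated independently: no ontology-graph (parent/child) correction
is applied, and only enrichment (not depletion) is tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .stats import bh_fdr

__all__ = [
    "AnnotationSet",
    "EnrichmentRow",
    "overrepresentation_pvalue",
    "fisher_overrepresentation",
    "enrich_table",
    "rows_to_frame",
]


def overrepresentation_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k), X ~ Hypergeom(N, K, n).

    The one-sided Fisher's exact test for overrepresentation of a term with
    K background members when k of n query genes hit it, out of N background
    genes.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K <= N and 0 <= n <= N")
    if not max(0, n + K - N) <= k <= min(n, K):
        raise ValueError(f"impossible table: k={k} with n={n}, K={K}, N={N}")
    return float(min(1.0, max(0.0, hypergeom.sf(k - 1, N, K, n))))

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationSet:
    """One annotation term and its member genes."""

    term_id: str
    term_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.term_id:
            raise ValueError("term_id must be non-empty")
        object.__setattr__(self, "members", frozenset(self.members))


@dataclass(frozen=True)
class EnrichmentRow:
    """Counts, fold enrichment and significance for one term.

    k of the n query genes hit the term; K of the N background genes are
    members. fold = (k/n)/(K/N); p is the hypergeometric upper tail
    P(X >= k); q is the BH-adjusted p across all tested terms.
    """

    term_id: str
    term_name: str
    k: int
    n_query: int
    K: int
    N_background: int
    fold_enrichment: float
    p: float
    q: float | None = None


def fisher_overrepresentation(
    query: Iterable[str], term: AnnotationSet, background: Iterable[str]
) -> EnrichmentRow:
    """One-sided Fisher's exact test for overrepresentation of a term.

    The query must be a subset of the background; term members outside the
    background are ignored. The p-value is the hypergeometric upper tail
    P(X >= k) for X ~ Hypergeom(N, K, n). Fold enrichment is 0 when k = 0.
    """
    q_set = set(query)
    bg = set(background)
    if not q_set:
        raise ValueError("query gene set is empty")
    if not bg:
        raise ValueError("background gene set is empty")
    stray = q_set - bg
    if stray:
        raise ValueError(
            f"{len(stray)} query genes are absent from the background "
            f"(e.g. {sorted(stray)[:3]})"
        )
    members = term.members & bg
    k = len(q_set & members)
    n = len(q_set)
    K = len(members)
    N = len(bg)
    p = overrepresentation_pvalue(k, n, K, N) if K > 0 else 1.0
    fold = (k / n) / (K / N) if k > 0 and K > 0 else 0.0
    return EnrichmentRow(term.term_id, term.term_name, k, n, K, N, fold, p)


def enrich_table(
    query: Iterable[str],
    annotations: Sequence[AnnotationSet],
    background: Iterable[str] | None = None,
    alpha: float = 0.05,
) -> list[EnrichmentRow]:
    """Test every annotation term and FDR-adjust across them.

    When no background is supplied, the union of all annotation members is
    used. Terms with no members in the background are skipped (logged).
    Rows come back sorted by q, then descending fold enrichment, then
    term_id for a stable order.
    """
    anns = list(annotations)
    if background is None:
        bg = set().union(*(a.members for a in anns)) if anns else set()
    else:
        bg = set(background)
    rows: list[EnrichmentRow] = []
    for term in anns:
        if not (term.members & bg):
            logger.info("term %s has no members in the background; skipped", term.term_id)
            continue
        rows.append(fisher_overrepresentation(query, term, bg))
    if not rows:
        return []
    qvals = bh_fdr([r.p for r in rows])
    adjusted = [
        EnrichmentRow(r.term_id, r.term_name, r.k, r.n_query, r.K, r.N_background,
                      r.fold_enrichment, r.p, float(qv))
        for r, qv in zip(rows, qvals)
    ]
    adjusted.sort(key=lambda r: (r.q, -r.fold_enrichment, r.term_id))
    return adjusted


def rows_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    """Tabulate enrichment rows for TSV output."""
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "k": r.k,
                "n_query": r.n_query,
                "K": r.K,
                "N_background": r.N_background,
                "fold_enrichment": r.fold_enrichment,
                "p": r.p,
                "q": r.q,
            }
            for r in rows
        ],
        columns=["term_id", "term_name", "k", "n_query", "K", "N_background",
                 "fold_enrichment", "p", "q"],
    )
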