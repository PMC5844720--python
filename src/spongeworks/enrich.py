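"""Hypergeometric over-representation analysis of term annotations.

For a selection of n genes from a universe of N, a term annotating K
universe genes, and an overlap of k selected genes, the enrichment p-value
is the upper tail P(X >= k) of Hypergeometric(N, K, n), inclusive of the
observed overlap.  The enrichment factor is (k/n)/(K/N) — the ratio of the
term's frequency among selected genes to its frequency in the universe.
Multiplicity is controlled with Benjamini–Hochberg (no pi0 estimation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom

from .diffexpr import bh_adjust

__all__ = ["TermAnnotation", "EnrichmentResult", "hypergeom_enrich", "top_terms"]


@dataclass(frozen=True)
class TermAnnotation:
    """One term (GO category / pathway) and its member genes."""

    term_id: str
    name: str
    namespace: str  # e.g. GO:BP, KEGG
    members: frozenset[str]


@dataclass
class EnrichmentResult:
    term_id: str
    name: str
    namespace: str
    k: int  # selected genes annotated to the term
    n: int  # selected genes in the universe
    K: int  # universe genes annotated to the term
    N: int  # universe size
    p: float
    q: float = float("nan")

    @property
    def enrichment_factor(self) -> float:
        if self.K == 0 or self.n == 0:
            return float("nan")
        return (self.k / self.n) / (self.K / self.N)

    @property
    def significant(self) -> bool:
        return self.q < 0.05


def hypergeom_enrich(
    selected: Iterable[str],
    annotation: Sequence[TermAnnotation],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Test every term for over-representation among the selected genes.

    The selection is intersected with the universe, as are term members;
    terms with no universe member are skipped.
    """
    universe_set = frozenset(universe)
    if not universe_set:
        raise ValueError("empty universe")
    sel = frozenset(selected) & universe_set
    N = len(universe_set)
    n = len(sel)
    results: list[EnrichmentResult] = []
    for term in annotation:
        members = term.members & universe_set
        K = len(members)
        if K == 0:
            continue
        k = len(members & sel)
        # inclusive upper tail P(X >= k)
        p = float(hypergeom.sf(k - 1, N, K, n))
        p = min(1.0, max(p, 0.0))
        results.append(
            EnrichmentResult(
                term_id=term.term_id,
                name=term.name,
                namespace=term.namespace,
                k=k,
                n=n,
                K=K,
                N=N,
                p=p,
            )
        )
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def top_terms(
    results: Sequence[EnrichmentResult], top_n: int = 20, min_genes: int = 4
) -> list[EnrichmentResult]:
    """Rank terms by enrichment factor; keep terms with >= ``min_genes`` hits.

    Ties are broken by ascending p, then term id, and the top ``top_n``
    qualifying terms are returned.
    """
    qualifying = [r for r in results if r.k >= min_genes]
    ranked = sorted(
        qualifying, key=lambda r: (-r.enrichment_factor, r.p, r.term_id)
    )
    return ranked[:top_n]
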