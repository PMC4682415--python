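"""Over-representation analysis of annotation terms among subnetwork genes.

For each annotation term (pathway, disease, drug or GWAS trait) sharing at
least ``min_overlap`` genes with the subnetwork, a one-sided Fisher exact
p-value is computed: the upper tail P(X >= overlap) of the hypergeometric
distribution over the gene universe.  The four contingency counts and the
overlapping gene list are reported so the corresponding Venn diagram is
fully reconstructable.

The tested gene set defaults to *all* subnetwork nodes (candidates,
targets, interactors, intermediates); ``gene_set="candidates"`` restricts
it to the query's candidate genes.  The universe defaults to all genes in
the interactome store; ``universe="catalogs"`` uses the union of catalog
genes instead.  Raw p-values are reported by default; Benjamini-Hochberg
adjusted values can be appended on request.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom

from .build import Subnetwork
from .store import AnnotationCatalog

__all__ = ["EnrichmentResult", "fisher_upper_tail", "enrich"]


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher exact result for one term.

    ``counts`` is (network_only, term_only, overlap, neither); the four
    counts sum to ``universe_size`` and parameterize the Venn diagram.
    """

    term: str
    category: str
    p_value: float
    overlap_genes: frozenset[str]
    counts: tuple[int, int, int, int]
    universe_size: int
    p_adjusted: float | None = None

    def as_dict(self) -> dict:
        return {
            "term": self.term,
            "category": self.category,
            "p_value": self.p_value,
            "overlap_genes": sorted(self.overlap_genes),
            "counts": list(self.counts),
            "universe_size": self.universe_size,
            "p_adjusted": self.p_adjusted,
        }


def fisher_upper_tail(overlap: int, set_a: int, set_b: int, universe: int) -> float:
    """One-sided Fisher exact p-value: P(X >= overlap) for
    X ~ Hypergeometric(universe, set_a, set_b).

    Stable for universes up to ~1e5 (survival function evaluated in log
    space internally by scipy).  ``overlap = 0`` returns exactly 1.0.
    """
    if not (0 <= overlap <= min(set_a, set_b)):
        raise ValueError(
            f"impossible counts: overlap={overlap}, set_a={set_a}, set_b={set_b}"
        )
    if set_a > universe or set_b > universe:
        raise ValueError("set sizes exceed the universe")
    if set_a + set_b - overlap > universe:
        raise ValueError("counts exceed the universe (negative 'neither' cell)")
    if overlap == 0:
        return 1.0
    p = float(hypergeom.sf(overlap - 1, universe, set_a, set_b))
    return min(p, 1.0)


def enrich(
    network: Subnetwork,
    catalogs: list[AnnotationCatalog],
    universe: str | frozenset[str] = "store",
    min_overlap: int = 1,
    gene_set: str = "network",
    adjust: bool = False,
) -> list[EnrichmentResult]:
    """Fisher-exact over-representation of catalog terms in the subnetwork.

    Returns one result per term with overlap >= ``min_overlap``, sorted
    ascending by p-value within each category (categories in input order).
    When ``adjust`` is true, Benjamini-Hochberg adjusted p-values are
    computed within each category and attached as ``p_adjusted``.
    """
    if gene_set == "network":
        genes = set(network.node_keys)
    elif gene_set == "candidates":
        genes = set(network.query.candidates)
    else:
        raise ValueError("gene_set must be 'network' or 'candidates'")

    if universe == "store":
        uni = set(network.store.keys)
    elif universe == "catalogs":
        uni = set()
        for cat in catalogs:
            for members in cat.terms.values():
                uni |= members
        uni |= genes
    else:
        uni = set(universe)
        if not genes <= uni:
            raise ValueError("network gene set is not contained in the universe")
    if not uni:
        raise ValueError("empty enrichment universe")
    n_universe = len(uni)
    genes &= uni

    results: list[EnrichmentResult] = []
    for cat in catalogs:
        unknown = {
            g for members in cat.terms.values() for g in members if g not in uni
        }
        if universe == "store" and unknown:
            raise ValueError(
                f"catalog {cat.provenance!r} carries genes outside the store "
                f"universe: {sorted(unknown)[:5]}"
            )
        cat_results: list[EnrichmentResult] = []
        for term in sorted(cat.terms):
            members = cat.terms[term] & uni
            overlap_genes = frozenset(genes & members)
            k = len(overlap_genes)
            if k < min_overlap:
                continue
            a, b = len(genes), len(members)
            p = fisher_upper_tail(k, a, b, n_universe)
            cat_results.append(
                EnrichmentResult(
                    term=term,
                    category=cat.category,
                    p_value=p,
                    overlap_genes=overlap_genes,
                    counts=(a - k, b - k, k, n_universe - a - b + k),
                    universe_size=n_universe,
                )
            )
        cat_results.sort(key=lambda r: (r.p_value, r.term))
        if adjust and cat_results:
            from statsmodels.stats.multitest import multipletests

            _, padj, _, _ = multipletests(
                [r.p_value for r in cat_results], method="fdr_bh"
            )
            cat_results = [
                EnrichmentResult(
                    term=r.term,
                    category=r.category,
                    p_value=r.p_value,
                    overlap_genes=r.overlap_genes,
                    counts=r.counts,
                    universe_size=r.universe_size,
                    p_adjusted=float(q),
                )
                for r, q in zip(cat_results, padj)
            ]
        results.extend(cat_results)
    return results
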