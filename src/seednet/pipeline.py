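"""End-to-end analysis: resolve -> build -> connectivity (+ baselines) ->
enrichment -> results document.  The CLI is a thin shell over this."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .build import GeneSetQuery, Subnetwork, build_subnetwork
from .enrichment import EnrichmentResult, enrich
from .io import ResultsDocument, document_from_run
from .stats import (
    DEFAULT_REPLICATES,
    DEFAULT_SENTINEL,
    BaselineTable,
    ConnectivityReport,
    compute_connectivity,
    random_baseline,
)
from .store import AnnotationCatalog, Interactome, resolve_genes

__all__ = ["AnalysisRun", "run_analysis"]

logger = logging.getLogger("seednet")


@dataclass
class AnalysisRun:
    """All artifacts of one pipeline execution."""

    query: GeneSetQuery
    rejected: tuple[tuple[str, str], ...]
    network: Subnetwork
    connectivity: ConnectivityReport
    baseline: BaselineTable
    enrichment: list[EnrichmentResult]
    document: ResultsDocument


def run_analysis(
    store: Interactome,
    candidate_tokens: list[str],
    target_tokens: list[str] | None = None,
    catalogs: list[AnnotationCatalog] | None = None,
    sentinel: int = DEFAULT_SENTINEL,
    replicates: int = DEFAULT_REPLICATES,
    seed: int | None = None,
    title: str = "",
    notes: str = "",
    induced_edges: bool = False,
    gene_set: str = "network",
    adjust: bool = False,
) -> AnalysisRun:
    """Run the full analysis for one or two gene lists.

    Tokens are resolved against the store (partial rejection is reported,
    total rejection raises); the subnetwork, connectivity statistics with
    their random baseline, and per-catalog enrichment are computed and
    assembled into a validated results document.
    """
    res_c = resolve_genes(candidate_tokens, store)
    rejected = list(res_c.rejected)
    targets = None
    if target_tokens is not None:
        res_t = resolve_genes(target_tokens, store)
        rejected += list(res_t.rejected)
        targets = res_t.resolved
    for token, reason in rejected:
        logger.warning("rejected input gene %r (%s)", token, reason)
    logger.info(
        "resolved %d candidate(s)%s, rejected %d token(s)",
        len(res_c.resolved),
        f" and {len(targets)} target(s)" if targets else "",
        len(rejected),
    )

    query = GeneSetQuery(candidates=res_c.resolved, targets=targets)
    network = build_subnetwork(store, query, induced_edges=induced_edges)
    logger.info(
        "subnetwork: %d nodes, %d edges, %d logged paths",
        len(network.nodes),
        len(network.edges),
        len(network.path_log),
    )
    connectivity = compute_connectivity(store, query, sentinel=sentinel)
    baseline = random_baseline(
        store, query, replicates=replicates, seed=seed, sentinel=sentinel
    )
    enrichment = enrich(
        network, catalogs or [], gene_set=gene_set, adjust=adjust
    )
    logger.info(
        "connectivity: min=%g avg=%.2f disconnected=%g over %g pair(s); "
        "%d enriched term(s)",
        connectivity.min_spl,
        connectivity.avg_spl,
        connectivity.disconnected_candidates,
        connectivity.pair_count,
        len(enrichment),
    )
    document = document_from_run(
        network,
        connectivity,
        baseline,
        enrichment,
        rejected=tuple(rejected),
        title=title,
        notes=notes,
        seed=seed,
    )
    return AnalysisRun(
        query=query,
        rejected=tuple(rejected),
        network=network,
        connectivity=connectivity,
        baseline=baseline,
        enrichment=enrichment,
        document=document,
    )
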