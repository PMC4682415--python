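"""Exporters: SIF, plain-text gene lists, GraphML, and the JSON results
document.

The results document is the self-contained record of one analysis run —
query echo, subnetwork, connectivity report with its random baseline
table, and per-category enrichment results — validated against a
versioned schema (pydantic models) and serialized with stable field
ordering so that write -> read -> write is byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .build import PathRecord, Subnetwork
from .enrichment import EnrichmentResult
from .stats import BaselineTable, ConnectivityReport

__all__ = [
    "SchemaError",
    "write_sif",
    "write_gene_list",
    "write_graphml",
    "ResultsDocument",
    "document_from_run",
    "write_results",
    "read_results",
]

logger = logging.getLogger("seednet")

SCHEMA_VERSION = "1"
NAMESPACES = ("symbol", "entrez", "uniprot")
ROLES = ("candidate", "target", "both", "interactor", "intermediate")


class SchemaError(ValueError):
    """A results document failed schema validation."""


# ---------------------------------------------------------------------------
# SIF / gene list / GraphML


def write_sif(network: Subnetwork, path, scope: str = "entire") -> None:
    """Write a Cytoscape SIF file: one ``geneA <TAB> pp <TAB> geneB`` line
    per edge, lexicographically ordered; nodes not covered by any emitted
    edge appear as bare single-token lines so they survive a round-trip.

    ``scope="shortest_paths_only"`` restricts to edges on logged shortest
    paths (seed nodes off every path are still emitted as bare lines).
    """
    if scope not in ("entire", "shortest_paths_only"):
        raise ValueError("scope must be 'entire' or 'shortest_paths_only'")
    if not network.nodes:
        raise ValueError("cannot export an empty subnetwork")
    if scope == "entire":
        edges = sorted(network.edges)
        covered = {n for e in edges for n in e}
        bare = sorted(set(network.nodes) - covered)
    else:
        edges = sorted(network.path_edges)
        covered = {n for e in edges for n in e}
        bare = sorted(network.seed_keys - covered)
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\tpp\t{b}\n")
        for n in bare:
            fh.write(f"{n}\n")


def write_gene_list(network: Subnetwork, namespace: str, path) -> int:
    """Write subnetwork genes one identifier per line (deduplicated,
    sorted) in the requested namespace.

    A gene lacking that namespace falls back to its canonical key; the
    number of such fallbacks is returned and logged as a warning.
    """
    if namespace not in NAMESPACES:
        raise ValueError(f"namespace must be one of {NAMESPACES}")
    out: set[str] = set()
    missing = 0
    for key in network.nodes:
        ident = network.store.record(key).identifier(namespace)
        if ident is None:
            missing += 1
            ident = key
        out.add(ident)
    if missing:
        logger.warning(
            "%d gene(s) lack a %s identifier; canonical keys emitted", missing, namespace
        )
    Path(path).write_text("".join(f"{i}\n" for i in sorted(out)))
    return missing


def write_graphml(network: Subnetwork, path) -> None:
    """Write the subnetwork as GraphML with a ``role`` node attribute."""
    G = nx.Graph()
    for key, role in sorted(network.nodes.items()):
        G.add_node(key, role=role)
    G.add_edges_from(sorted(network.edges))
    nx.write_graphml(G, path)


# ---------------------------------------------------------------------------
# results document schema


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PathRecordDoc(_Model):
    source: str
    dest: str
    nodes: list[str] = Field(min_length=1)


class SubnetworkDoc(_Model):
    nodes: dict[str, str]
    edges: list[tuple[str, str]]
    path_log: list[PathRecordDoc]

    def to_roles_check(self) -> None:
        bad = {r for r in self.nodes.values() if r not in ROLES}
        if bad:
            raise SchemaError(f"unknown node roles: {sorted(bad)}")


class ConnectivityDoc(_Model):
    min_spl: float
    avg_spl: float
    disconnected_candidates: float
    pair_count: float
    sentinel: int


class BaselineDoc(_Model):
    replicates: int = Field(ge=1)
    seed: int | None
    rows: dict[str, ConnectivityDoc]


class EnrichmentDoc(_Model):
    term: str
    category: str
    p_value: float = Field(gt=0.0, le=1.0)
    overlap_genes: list[str]
    counts: tuple[int, int, int, int]
    universe_size: int = Field(ge=1)
    p_adjusted: float | None = None


class QueryDoc(_Model):
    candidates: list[str] = Field(min_length=1)
    targets: list[str] | None = None
    rejected: list[tuple[str, str]] = Field(default_factory=list)


class MetadataDoc(_Model):
    tool: str = "seednet"
    version: str = "0.1.0"
    seed: int | None = None
    created: str = ""


class ResultsDocument(_Model):
    """Self-contained record of one analysis run (schema version 1)."""

    schema_version: str = SCHEMA_VERSION
    title: str = ""
    notes: str = ""
    query: QueryDoc
    subnetwork: SubnetworkDoc
    connectivity: ConnectivityDoc
    baseline: BaselineDoc
    enrichment: dict[str, list[EnrichmentDoc]]
    metadata: MetadataDoc = Field(default_factory=MetadataDoc)


def document_from_run(
    network: Subnetwork,
    connectivity: ConnectivityReport,
    baseline: BaselineTable,
    enrichment: list[EnrichmentResult],
    rejected: tuple[tuple[str, str], ...] = (),
    title: str = "",
    notes: str = "",
    seed: int | None = None,
    created: str = "",
) -> ResultsDocument:
    """Assemble a validated results document from in-memory run artifacts."""
    by_category: dict[str, list[EnrichmentDoc]] = {}
    for r in enrichment:
        by_category.setdefault(r.category, []).append(
            EnrichmentDoc(
                term=r.term,
                category=r.category,
                p_value=r.p_value,
                overlap_genes=sorted(r.overlap_genes),
                counts=r.counts,
                universe_size=r.universe_size,
                p_adjusted=r.p_adjusted,
            )
        )
    return ResultsDocument(
        title=title,
        notes=notes,
        query=QueryDoc(
            candidates=list(network.query.candidates),
            targets=list(network.query.targets) if network.query.targets else None,
            rejected=[tuple(r) for r in rejected],
        ),
        subnetwork=SubnetworkDoc(
            nodes=dict(sorted(network.nodes.items())),
            edges=sorted(network.edges),
            path_log=[
                PathRecordDoc(source=p.source, dest=p.dest, nodes=list(p.nodes))
                for p in network.path_log
            ],
        ),
        connectivity=ConnectivityDoc(**connectivity.as_dict()),
        baseline=BaselineDoc(
            replicates=baseline.replicates,
            seed=baseline.seed,
            rows={k: ConnectivityDoc(**v.as_dict()) for k, v in baseline.rows.items()},
        ),
        enrichment=by_category,
        metadata=MetadataDoc(seed=seed, created=created),
    )


def write_results(doc: ResultsDocument, path) -> None:
    """Serialize a results document as stable, diff-friendly JSON."""
    payload = doc.model_dump(mode="json")
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_results(path) -> ResultsDocument:
    """Load and schema-validate a results document."""
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise SchemaError(f"cannot read results document {path}: {exc}") from exc
    try:
        doc = ResultsDocument.model_validate(payload)
    except ValidationError as exc:
        raise SchemaError(f"results document {path} violates the schema: {exc}") from exc
    doc.subnetwork.to_roles_check()
    return doc
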