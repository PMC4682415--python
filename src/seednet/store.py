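"""Interactome store: identifier mapping, edge-list loading, annotation catalogs.

The store holds an undirected simple graph of protein-protein interactions
over canonical gene keys, together with a three-namespace identifier table
(HUGO-style symbol, Entrez integer ID, UniProt accession).  All downstream
modules (subnetwork construction, connectivity statistics, enrichment) work
on canonical keys and resolve user-facing identifiers through this store.

Conventions
-----------
* Symbols match case-insensitively.
* Entrez IDs compare numerically.
* UniProt accessions match case-insensitively with any isoform suffix
  (``-2`` etc.) stripped.
* An identifier value claimed by more than one gene record is *ambiguous*:
  it is removed from the lookup index at load time (recorded in the load
  report) and any query token hitting it is rejected with reason
  ``"ambiguous"``.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "GeneRecord",
    "EdgeListDialect",
    "DIALECTS",
    "LoadReport",
    "Interactome",
    "AnnotationCatalog",
    "Resolution",
    "StoreError",
    "DialectError",
    "EmptyQueryError",
    "load_id_table",
    "load_interactome",
    "resolve_genes",
    "load_catalog",
]

CATEGORIES = ("pathway", "disease", "drug", "gwas")

#: namespace resolution order; earlier namespaces win for ambiguous tokens
DEFAULT_PRECEDENCE = ("symbol", "entrez", "uniprot")

_MI_CODE_RE = re.compile(r"(\d{4})")


class StoreError(Exception):
    """Base error for interactome-store loading and resolution failures."""


class DialectError(StoreError):
    """Edge-list file does not conform to the declared column dialect."""


class EmptyQueryError(StoreError):
    """Every token of a gene query was rejected (nothing to analyze)."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene with its identifiers in up to three namespaces.

    At least one of ``symbol``, ``entrez``, ``uniprot`` is present; ``key``
    is the canonical identifier used throughout the package.
    """

    key: str
    symbol: str | None = None
    entrez: int | None = None
    uniprot: str | None = None

    def identifier(self, namespace: str) -> str | None:
        """Return this gene's identifier in ``namespace`` (as a string)."""
        if namespace == "symbol":
            return self.symbol
        if namespace == "entrez":
            return None if self.entrez is None else str(self.entrez)
        if namespace == "uniprot":
            return self.uniprot
        raise ValueError(f"unknown namespace: {namespace!r}")


@dataclass(frozen=True)
class EdgeListDialect:
    """Column layout of a tab-separated interaction file.

    ``col_a``/``col_b`` are 0-based indices of the two interactor columns;
    ``type_col`` (optional) carries an interaction-type code (e.g. a PSI-MI
    code) used by the interaction-type filter; ``namespace`` declares which
    identifier namespace the interactor columns use (``"auto"`` resolves
    through the normal precedence order).
    """

    col_a: int = 0
    col_b: int = 1
    type_col: int | None = None
    has_header: bool = False
    namespace: str = "auto"

    @property
    def min_columns(self) -> int:
        cols = [self.col_a, self.col_b]
        if self.type_col is not None:
            cols.append(self.type_col)
        return max(cols) + 1


#: presets for the flat-file layouts the package reads out of the box
DIALECTS: dict[str, EdgeListDialect] = {
    # two identifier columns, optional third type column
    "simple": EdgeListDialect(0, 1, None),
    "simple-typed": EdgeListDialect(0, 1, 2),
    # HPRD binary-PPI flat file: symbol at columns 0 and 3
    "hprd-flat": EdgeListDialect(0, 3, None, namespace="symbol"),
    # BioGRID tab: Entrez IDs at columns 1 and 2, interaction-type code
    # (PSI-MI) at column 11, header line present
    "biogrid-tab": EdgeListDialect(1, 2, 11, has_header=True, namespace="entrez"),
}


@dataclass
class LoadReport:
    """Row accounting for a load operation (read / kept / dropped + reasons)."""

    rows_read: int = 0
    rows_kept: int = 0
    dropped: Counter = field(default_factory=Counter)
    notes: list[str] = field(default_factory=list)

    def drop(self, reason: str, n: int = 1) -> None:
        self.dropped[reason] += n

    @property
    def rows_dropped(self) -> int:
        return sum(self.dropped.values())

    def as_dict(self) -> dict:
        return {
            "rows_read": self.rows_read,
            "rows_kept": self.rows_kept,
            "dropped": dict(self.dropped),
            "notes": list(self.notes),
        }


@dataclass(frozen=True)
class Resolution:
    """Outcome of resolving identifier tokens against a store."""

    resolved: tuple[str, ...]
    rejected: tuple[tuple[str, str], ...]  # (token, reason); reason in {unknown, ambiguous}


class Interactome:
    """Canonicalized simple PPI graph plus the three-namespace ID table.

    Parameters
    ----------
    records
        Gene records; canonical keys must be unique.
    edges
        Iterable of unordered canonical-key pairs.  Self-loops and
        duplicates are rejected here (the loader drops them earlier and
        accounts for them in the load report).
    precedence
        Namespace order tried when resolving tokens.
    """

    def __init__(
        self,
        records: list[GeneRecord],
        edges=(),
        precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
        load_report: LoadReport | None = None,
    ):
        self.precedence = tuple(precedence)
        self.load_report = load_report or LoadReport()
        self._records: dict[str, GeneRecord] = {}
        self._index: dict[str, dict[str, str]] = {"symbol": {}, "entrez": {}, "uniprot": {}}
        self._ambiguous: dict[str, set[str]] = {"symbol": set(), "entrez": set(), "uniprot": set()}
        for rec in records:
            if rec.key in self._records:
                raise StoreError(f"duplicate canonical key: {rec.key}")
            if rec.symbol is None and rec.entrez is None and rec.uniprot is None:
                raise StoreError(f"record {rec.key} has no identifier in any namespace")
            self._records[rec.key] = rec
            self._index_record(rec)
        self.graph = nx.Graph()
        self.graph.add_nodes_from(self._records)
        for a, b in edges:
            if a == b:
                raise StoreError(f"self-loop not allowed in store: {a}")
            if a not in self._records or b not in self._records:
                raise StoreError(f"edge references unknown gene: ({a}, {b})")
            self.graph.add_edge(a, b)

    # -- indexing -----------------------------------------------------------

    def _index_record(self, rec: GeneRecord) -> None:
        for ns, value in (
            ("symbol", rec.symbol),
            ("entrez", rec.entrez),
            ("uniprot", rec.uniprot),
        ):
            if value is None:
                continue
            norm = _normalize(ns, str(value))
            idx = self._index[ns]
            if norm in self._ambiguous[ns]:
                continue
            if norm in idx and idx[norm] != rec.key:
                # value claimed by two records: poison it for lookups
                del idx[norm]
                self._ambiguous[ns].add(norm)
                self.load_report.notes.append(f"ambiguous {ns} value: {value}")
                self.load_report.drop(f"ambiguous_{ns}")
            else:
                idx[norm] = rec.key

    # -- introspection ------------------------------------------------------

    @property
    def keys(self) -> frozenset[str]:
        return frozenset(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, key: str) -> bool:
        return key in self._records

    def record(self, key: str) -> GeneRecord:
        return self._records[key]

    def records(self):
        return self._records.values()

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges()}

    def neighbors(self, key: str):
        return self.graph.neighbors(key)

    # -- resolution ---------------------------------------------------------

    def lookup(self, token: str) -> tuple[str | None, str | None]:
        """Resolve a single token; return ``(key, None)`` or ``(None, reason)``."""
        token = token.strip()
        if not token:
            return None, "unknown"
        for ns in self.precedence:
            norm = _normalize(ns, token)
            if norm is None:
                continue
            if norm in self._ambiguous[ns]:
                return None, "ambiguous"
            key = self._index[ns].get(norm)
            if key is not None:
                return key, None
        return None, "unknown"

    def resolve(self, tokens, raise_on_empty: bool = True) -> Resolution:
        """Resolve identifier tokens to canonical keys.

        Duplicate hits collapse preserving first occurrence.  Rejected
        tokens carry a reason (``unknown`` or ``ambiguous``).  When every
        token is rejected an :class:`EmptyQueryError` is raised (unless
        ``raise_on_empty`` is False).
        """
        tokens = [t.strip() for t in tokens if t and t.strip()]
        if not tokens:
            raise EmptyQueryError("no identifier tokens supplied")
        resolved: list[str] = []
        seen: set[str] = set()
        rejected: list[tuple[str, str]] = []
        for token in tokens:
            key, reason = self.lookup(token)
            if key is None:
                rejected.append((token, reason))
            elif key not in seen:
                seen.add(key)
                resolved.append(key)
        if not resolved and raise_on_empty:
            raise EmptyQueryError(
                f"all {len(tokens)} token(s) were rejected: "
                + ", ".join(f"{t} ({r})" for t, r in rejected[:10])
            )
        return Resolution(tuple(resolved), tuple(rejected))

    # -- export -------------------------------------------------------------

    def write_edge_list(self, path) -> None:
        """Write the edge set as a two-column TSV (round-trips through
        :func:`load_interactome` with the ``simple`` dialect)."""
        with open(path, "w") as fh:
            fh.write("# seednet edge list\n")
            for a, b in sorted(self.edges):
                fh.write(f"{a}\t{b}\n")


@dataclass
class AnnotationCatalog:
    """Term -> gene-set mapping for one annotation category.

    ``category`` is one of pathway / disease / drug / gwas; ``terms`` maps a
    term name to the set of canonical keys annotated with it (every term
    non-empty); ``provenance`` is a free-text source label.
    """

    category: str
    terms: dict[str, frozenset[str]]
    provenance: str = ""
    load_report: LoadReport = field(default_factory=LoadReport)

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}, got {self.category!r}")
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} has no genes")


# ---------------------------------------------------------------------------
# normalization helpers


def _normalize(namespace: str, value: str) -> str | None:
    """Normalize an identifier for index lookup; None if not valid in ns."""
    value = value.strip()
    if namespace == "symbol":
        return value.upper()
    if namespace == "entrez":
        try:
            return str(int(value))
        except ValueError:
            return None
    if namespace == "uniprot":
        return value.upper().split("-")[0]  # strip isoform suffix
    raise ValueError(f"unknown namespace: {namespace!r}")


def _type_codes(cell: str) -> set[str]:
    """Extract candidate interaction-type codes from a type-column cell.

    Accepts bare codes ("0417"), prefixed PSI-MI forms ("MI:0417",
    'psi-mi:"MI:0417"(...)'), or arbitrary text containing 4-digit codes.
    """
    codes = set(_MI_CODE_RE.findall(cell))
    codes.add(cell.strip())
    return codes


# ---------------------------------------------------------------------------
# loaders


def load_id_table(path, precedence: tuple[str, ...] = DEFAULT_PRECEDENCE) -> list[GeneRecord]:
    """Read the gene identifier table (TSV, header symbol/entrez/uniprot).

    Empty cells mean the gene lacks that identifier; each row must carry at
    least one.  The canonical key is the symbol when present, otherwise
    ``ENTREZ:<id>``, otherwise the UniProt accession.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype="string", comment="#")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise StoreError(f"cannot read ID table {path}: {exc}") from exc
    cols = {c.strip().lower() for c in df.columns}
    if not {"symbol", "entrez", "uniprot"} <= cols:
        raise DialectError(
            f"ID table {path} must have header columns symbol/entrez/uniprot, got {sorted(cols)}"
        )
    df.columns = [c.strip().lower() for c in df.columns]
    records: list[GeneRecord] = []
    for row in df.itertuples(index=False):
        symbol = None if pd.isna(row.symbol) or not str(row.symbol).strip() else str(row.symbol).strip()
        entrez = None
        if not pd.isna(row.entrez) and str(row.entrez).strip():
            try:
                entrez = int(str(row.entrez).strip())
            except ValueError as exc:
                raise StoreError(f"non-numeric Entrez ID {row.entrez!r} in {path}") from exc
        uniprot = None if pd.isna(row.uniprot) or not str(row.uniprot).strip() else str(row.uniprot).strip()
        if symbol is None and entrez is None and uniprot is None:
            continue
        key = symbol.upper() if symbol else (f"ENTREZ:{entrez}" if entrez is not None else uniprot.upper())
        records.append(GeneRecord(key=key, symbol=symbol, entrez=entrez, uniprot=uniprot))
    if not records:
        raise StoreError(f"ID table {path} contains no usable rows")
    return records


def load_interactome(
    edge_list_path,
    id_table_path,
    interaction_type_filter: set[str] | None = None,
    dialect: str | EdgeListDialect = "simple",
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> Interactome:
    """Load and canonicalize an interactome from flat files.

    Parameters
    ----------
    edge_list_path
        Tab-separated interaction file; ``#`` comment lines ignored.
    id_table_path
        TSV with header symbol/entrez/uniprot (empty cell = absent).
    interaction_type_filter
        When given and the dialect declares a type column, only rows whose
        type cell carries one of these codes (e.g. ``{"0417"}`` for binary
        biophysical interactions) are kept.
    dialect
        Preset name (``simple``, ``simple-typed``, ``hprd-flat``,
        ``biogrid-tab``) or an explicit :class:`EdgeListDialect`.

    Returns a simple graph: self-loops dropped, duplicate edges collapsed,
    edges only between genes resolvable through the ID table.  Row-level
    accounting is retrievable via ``store.load_report``.
    """
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError:
            raise DialectError(f"unknown dialect {dialect!r}; presets: {sorted(DIALECTS)}")
    report = LoadReport()
    records = load_id_table(id_table_path, precedence)
    store = Interactome(records, precedence=precedence, load_report=report)

    try:
        with open(edge_list_path) as fh:
            lines = fh.readlines()
    except OSError as exc:
        raise StoreError(f"cannot read edge list {edge_list_path}: {exc}") from exc

    rows: list[list[str]] = []
    for line in lines:
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        rows.append(line.split("\t"))
    if dialect.has_header:
        if not rows:
            raise DialectError(f"{edge_list_path}: empty file but dialect declares a header")
        header = rows.pop(0)
        if len(header) < dialect.min_columns:
            raise DialectError(
                f"{edge_list_path}: header has {len(header)} columns, "
                f"dialect needs {dialect.min_columns}"
            )

    seen_edges: set[frozenset[str]] = set()
    edges: list[tuple[str, str]] = []
    for row in rows:
        report.rows_read += 1
        if len(row) < max(dialect.col_a, dialect.col_b) + 1:
            report.drop("malformed")
            continue
        if interaction_type_filter is not None and dialect.type_col is not None:
            if len(row) <= dialect.type_col:
                report.drop("type_filtered")
                continue
            codes = _type_codes(row[dialect.type_col])
            if not codes & set(interaction_type_filter):
                report.drop("type_filtered")
                continue
        key_a = _resolve_edge_token(store, row[dialect.col_a], dialect.namespace)
        key_b = _resolve_edge_token(store, row[dialect.col_b], dialect.namespace)
        if key_a is None or key_b is None:
            report.drop("unresolved")
            continue
        if key_a == key_b:
            report.drop("self_loop")
            continue
        pair = frozenset((key_a, key_b))
        if pair in seen_edges:
            report.drop("duplicate")
            continue
        seen_edges.add(pair)
        edges.append((key_a, key_b))
        report.rows_kept += 1

    if report.rows_read and not edges:
        raise StoreError(f"{edge_list_path}: no resolvable interaction rows")
    store.graph.add_edges_from(edges)
    return store


def _resolve_edge_token(store: Interactome, token: str, namespace: str) -> str | None:
    token = token.strip()
    if not token:
        return None
    if namespace == "auto":
        key, _ = store.lookup(token)
        return key
    norm = _normalize(namespace, token)
    if norm is None or norm in store._ambiguous[namespace]:
        return None
    return store._index[namespace].get(norm)


def resolve_genes(tokens, store: Interactome) -> Resolution:
    """Validate identifier tokens against the store (symbol -> Entrez ->
    UniProt precedence, case-insensitive), collapsing duplicates.

    Raises :class:`EmptyQueryError` when every token is rejected; partial
    rejection is reported in ``Resolution.rejected``.
    """
    return store.resolve(tokens, raise_on_empty=True)


def load_catalog(path, category: str, store: Interactome, provenance: str = "") -> AnnotationCatalog:
    """Load a GMT-style annotation catalog (term TAB description TAB gene...).

    Gene tokens resolve as in :func:`resolve_genes`; tokens not in the store
    are dropped from their term (counted in the load report) and terms
    emptied by dropping are removed.
    """
    report = LoadReport()
    try:
        with open(path) as fh:
            lines = fh.readlines()
    except OSError as exc:
        raise StoreError(f"cannot read catalog {path}: {exc}") from exc
    terms: dict[str, frozenset[str]] = {}
    for line in lines:
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        report.rows_read += 1
        parts = line.split("\t")
        if len(parts) < 3:
            report.drop("malformed")
            continue
        term, _desc, tokens = parts[0].strip(), parts[1], parts[2:]
        if term in terms:
            report.drop("duplicate_term")
            continue
        res = store.resolve(tokens, raise_on_empty=False)
        n_dropped = len(res.rejected)
        if n_dropped:
            report.drop("unknown_gene_token", n_dropped)
        if not res.resolved:
            report.drop("empty_term")
            continue
        terms[term] = frozenset(res.resolved)
        report.rows_kept += 1
    if not terms:
        raise StoreError(f"catalog {path}: zero surviving terms")
    return AnnotationCatalog(category=category, terms=terms, provenance=provenance or str(path), load_report=report)
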