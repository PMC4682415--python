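"""Subnetwork construction from one or two seed gene sets.

Two recruitment modes mirror the one-set / two-set analysis contract:

* **Candidate-only** — every candidate gene recruits all of its immediate
  interactors, and, for each candidate, all other candidates at minimal
  positive shortest-path distance in the *full* interactome together with
  every node on every distinct shortest path to them.

* **Candidate + target** — candidates still recruit their immediate
  interactors, but shortest paths are sought only from each candidate to
  its closest target gene(s); candidate-to-candidate paths are not added
  and target interactors are not recruited.  Targets unreachable from every
  candidate remain in the network as isolated target nodes.

If a candidate ties between several nearest seeds, or several distinct
shortest paths to a seed exist, all of them are recruited.  Shortest paths
are always computed on the full interactome, never on the growing
subnetwork.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .store import Interactome

__all__ = [
    "GeneSetQuery",
    "PathRecord",
    "Subnetwork",
    "build_candidate_network",
    "build_candidate_target_network",
    "build_subnetwork",
]

#: node role precedence, highest first, when a node qualifies for several
ROLE_ORDER = ("both", "candidate", "target", "intermediate", "interactor")


@dataclass(frozen=True)
class GeneSetQuery:
    """A validated query: candidate keys and an optional target key set.

    Order is preserved (first occurrence); a key may appear in both sets,
    in which case its role is ``both``.
    """

    candidates: tuple[str, ...]
    targets: tuple[str, ...] | None = None

    def __post_init__(self):
        if not self.candidates:
            raise ValueError("query needs at least one candidate gene")
        if len(set(self.candidates)) != len(self.candidates):
            raise ValueError("duplicate candidate keys")
        if self.targets is not None:
            if not self.targets:
                raise ValueError("target set, when given, must be non-empty")
            if len(set(self.targets)) != len(self.targets):
                raise ValueError("duplicate target keys")

    @property
    def two_set(self) -> bool:
        return self.targets is not None

    def validate_against(self, store: Interactome) -> None:
        missing = [k for k in self.candidates if k not in store]
        if self.targets:
            missing += [k for k in self.targets if k not in store]
        if missing:
            raise KeyError(f"query keys not in store: {missing}")


@dataclass(frozen=True, order=True)
class PathRecord:
    """One recruited shortest path and the seed pair that justified it."""

    source: str
    dest: str
    nodes: tuple[str, ...]

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(
            tuple(sorted((a, b))) for a, b in zip(self.nodes, self.nodes[1:])
        )


@dataclass
class Subnetwork:
    """The constructed analysis network.

    ``nodes`` maps canonical key -> role in {candidate, target, both,
    interactor, intermediate}; ``edges`` is a set of unordered key pairs
    (stored as sorted tuples); ``path_log`` records every recruited
    shortest path with its justifying (source, destination) seed pair.
    """

    nodes: dict[str, str]
    edges: set[tuple[str, str]]
    path_log: tuple[PathRecord, ...]
    query: GeneSetQuery
    store: Interactome = field(repr=False)

    @property
    def node_keys(self) -> frozenset[str]:
        return frozenset(self.nodes)

    def nodes_with_role(self, role: str) -> frozenset[str]:
        return frozenset(k for k, r in self.nodes.items() if r == role)

    @property
    def path_edges(self) -> set[tuple[str, str]]:
        """Edges lying on at least one logged shortest path."""
        out: set[tuple[str, str]] = set()
        for rec in self.path_log:
            out.update(rec.edges)
        return out

    @property
    def seed_keys(self) -> frozenset[str]:
        seeds = set(self.query.candidates)
        if self.query.targets:
            seeds |= set(self.query.targets)
        return frozenset(seeds)


def _assign_role(
    key: str,
    candidates: set[str],
    targets: set[str],
    path_interior: set[str],
) -> str:
    if key in candidates and key in targets:
        return "both"
    if key in candidates:
        return "candidate"
    if key in targets:
        return "target"
    if key in path_interior:
        return "intermediate"
    return "interactor"


def _all_shortest_paths(G: nx.Graph, src: str, dst: str):
    return nx.all_shortest_paths(G, src, dst)


def build_candidate_network(
    store: Interactome, query: GeneSetQuery, induced_edges: bool = False
) -> Subnetwork:
    """Build the one-set subnetwork.

    Nodes are the candidates, all their direct interactors, and every node
    on any shortest path (in the full interactome) from each candidate to
    its nearest candidate neighbor(s); co-minimal neighbors and co-minimal
    paths are all included.  Edges are candidate-incident interactome edges
    plus edges on logged paths (set ``induced_edges=True`` for the full
    induced subgraph instead).  Isolated candidates are retained.
    """
    if query.two_set:
        raise ValueError("query carries targets; use build_candidate_target_network")
    query.validate_against(store)
    G = store.graph
    candidates = set(query.candidates)

    nodes: set[str] = set(candidates)
    edges: set[tuple[str, str]] = set()
    for c in query.candidates:
        for nbr in G.neighbors(c):
            nodes.add(nbr)
            edges.add(tuple(sorted((c, nbr))))

    path_log: list[PathRecord] = []
    for c in query.candidates:
        dist = nx.single_source_shortest_path_length(G, c)
        reachable = {o: d for o, d in dist.items() if o in candidates and d > 0}
        if not reachable:
            continue
        dmin = min(reachable.values())
        for other in sorted(o for o, d in reachable.items() if d == dmin):
            for path in _all_shortest_paths(G, c, other):
                rec = PathRecord(source=c, dest=other, nodes=tuple(path))
                path_log.append(rec)
                nodes.update(rec.nodes)
                edges.update(rec.edges)

    return _finalize(store, query, nodes, edges, path_log, induced_edges)


def build_candidate_target_network(
    store: Interactome, query: GeneSetQuery, induced_edges: bool = False
) -> Subnetwork:
    """Build the two-set subnetwork.

    Each candidate is linked to its minimally distant target(s) by all
    shortest interactome paths; candidate interactors are recruited, target
    interactors are not; every target appears as a node even when
    unreachable (isolated, role ``target``).  A gene in both sets acts as a
    candidate and is excluded from its own target search.
    """
    if not query.two_set:
        raise ValueError("query has no targets; use build_candidate_network")
    query.validate_against(store)
    G = store.graph
    candidates = set(query.candidates)
    targets = set(query.targets)

    nodes: set[str] = set(candidates) | targets
    edges: set[tuple[str, str]] = set()
    for c in query.candidates:
        for nbr in G.neighbors(c):
            nodes.add(nbr)
            edges.add(tuple(sorted((c, nbr))))

    path_log: list[PathRecord] = []
    for c in query.candidates:
        dist = nx.single_source_shortest_path_length(G, c)
        reachable = {t: d for t, d in dist.items() if t in targets and d > 0}
        if not reachable:
            continue
        dmin = min(reachable.values())
        for t in sorted(t for t, d in reachable.items() if d == dmin):
            for path in _all_shortest_paths(G, c, t):
                rec = PathRecord(source=c, dest=t, nodes=tuple(path))
                path_log.append(rec)
                nodes.update(rec.nodes)
                edges.update(rec.edges)

    return _finalize(store, query, nodes, edges, path_log, induced_edges)


def build_subnetwork(
    store: Interactome, query: GeneSetQuery, induced_edges: bool = False
) -> Subnetwork:
    """Dispatch to the one-set or two-set builder based on the query."""
    if query.two_set:
        return build_candidate_target_network(store, query, induced_edges)
    return build_candidate_network(store, query, induced_edges)


def _finalize(
    store: Interactome,
    query: GeneSetQuery,
    nodes: set[str],
    edges: set[tuple[str, str]],
    path_log: list[PathRecord],
    induced_edges: bool,
) -> Subnetwork:
    candidates = set(query.candidates)
    targets = set(query.targets) if query.targets else set()
    path_interior: set[str] = set()
    for rec in path_log:
        path_interior.update(rec.nodes[1:-1])
    roles = {
        k: _assign_role(k, candidates, targets, path_interior) for k in sorted(nodes)
    }
    if induced_edges:
        edges = {
            tuple(sorted((a, b)))
            for a, b in store.graph.subgraph(nodes).edges()
        }
    return Subnetwork(
        nodes=roles,
        edges=set(edges),
        path_log=tuple(path_log),
        query=query,
        store=store,
    )
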