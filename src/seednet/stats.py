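"""Connectivity statistics and random-gene-set baselines.

Three numbers summarize how tightly a query connects in the interactome:
the minimum shortest path length over seed pairs, the average shortest
path length, and the number of disconnected candidate genes.  Pairs with
no connecting path contribute a fixed sentinel hop count (default 17,
chosen for a human interactome snapshot as five edges beyond its observed
diameter; configurable for other interactomes).  Each unordered pair
contributes exactly once regardless of how many co-minimal paths exist.

In two-set mode the pairs are all candidate x target cross pairs (a gene
in both sets never pairs with itself); a target unreachable from *every*
candidate is excluded from the pair set entirely and does not inflate the
average, and only disconnected candidates are counted.

Baselines repeat the computation on randomly drawn gene sets of matched
size (uniform, without replacement, from the store's full gene universe)
and report per-scheme means over replicates; fractional mean disconnected
counts are expected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .build import GeneSetQuery
from .store import Interactome

__all__ = [
    "DEFAULT_SENTINEL",
    "DEFAULT_REPLICATES",
    "TWO_SET_SCHEMES",
    "CANDIDATE_ONLY_SCHEME",
    "ConnectivityReport",
    "BaselineTable",
    "UndefinedStatisticsError",
    "compute_connectivity",
    "random_baseline",
]

DEFAULT_SENTINEL = 17
DEFAULT_REPLICATES = 5

CANDIDATE_ONLY_SCHEME = "random"
TWO_SET_SCHEMES = ("candidate_to_random", "random_to_target", "random_to_random")


class UndefinedStatisticsError(ValueError):
    """Raised when the pair set is structurally empty (e.g. one candidate)."""


@dataclass(frozen=True)
class ConnectivityReport:
    """Summary of pairwise shortest-path structure for one query.

    ``min_spl``/``avg_spl`` are in unweighted hops (or the sentinel);
    ``disconnected_candidates`` counts candidates with no path to any
    counterpart; ``pair_count`` is the number of pairs averaged.
    """

    min_spl: float
    avg_spl: float
    disconnected_candidates: float
    pair_count: float
    sentinel: int = DEFAULT_SENTINEL

    def as_dict(self) -> dict:
        return {
            "min_spl": self.min_spl,
            "avg_spl": self.avg_spl,
            "disconnected_candidates": self.disconnected_candidates,
            "pair_count": self.pair_count,
            "sentinel": self.sentinel,
        }


@dataclass(frozen=True)
class BaselineTable:
    """Per-scheme mean connectivity over random replicates.

    ``rows`` maps scheme name -> mean report; candidate-only queries have
    the single scheme ``random``, two-set queries the three schemes
    ``candidate_to_random`` (random targets), ``random_to_target`` (random
    candidates) and ``random_to_random``.  ``replicate_reports`` keeps the
    raw per-replicate reports for inspection.
    """

    rows: dict[str, ConnectivityReport]
    replicates: int
    seed: int | None
    replicate_reports: dict[str, tuple[ConnectivityReport, ...]]

    def as_dict(self) -> dict:
        return {
            "replicates": self.replicates,
            "seed": self.seed,
            "rows": {name: row.as_dict() for name, row in self.rows.items()},
        }


def _pair_distances(
    store: Interactome, query: GeneSetQuery, sentinel: int
) -> tuple[list[float], int]:
    """Return (per-pair contributions, disconnected candidate count)."""
    G = store.graph
    candidates = list(query.candidates)
    dist_from = {
        c: nx.single_source_shortest_path_length(G, c) for c in candidates
    }

    if not query.two_set:
        if len(candidates) < 2:
            raise UndefinedStatisticsError(
                "candidate-only connectivity needs at least 2 candidates"
            )
        contributions: list[float] = []
        for a, b in itertools.combinations(candidates, 2):
            d = dist_from[a].get(b)
            contributions.append(float(d) if d is not None else float(sentinel))
        disconnected = sum(
            1
            for c in candidates
            if not any(o in dist_from[c] for o in candidates if o != c)
        )
        return contributions, disconnected

    targets = list(query.targets)
    # a target no candidate can reach is dropped from the pair set entirely
    def reachable(t: str) -> bool:
        return any(t in dist_from[c] for c in candidates if c != t)

    kept_targets = [t for t in targets if reachable(t)]
    contributions = []
    for c in candidates:
        for t in kept_targets:
            if c == t:
                continue  # a gene in both sets never pairs with itself
            d = dist_from[c].get(t)
            contributions.append(float(d) if d is not None else float(sentinel))
    disconnected = sum(
        1
        for c in candidates
        if not any(t in dist_from[c] for t in targets if t != c)
    )
    return contributions, disconnected


def compute_connectivity(
    store: Interactome,
    query: GeneSetQuery,
    sentinel: int = DEFAULT_SENTINEL,
) -> ConnectivityReport:
    """Compute min / average shortest path length and disconnected count.

    Distances are taken on the full interactome.  Each unordered candidate
    pair (one-set) or candidate x target cross pair (two-set, self-pairs
    excluded) contributes once: its hop count, or ``sentinel`` when no path
    exists.  Targets unreachable from every candidate are excluded before
    averaging; candidates are never excluded — a fully disconnected
    candidate contributes the sentinel for each of its pairs.
    """
    query.validate_against(store)
    contributions, disconnected = _pair_distances(store, query, sentinel)
    if not contributions:
        # every cross pair vanished (all targets unreachable): degenerate,
        # report sentinel-level connectivity over zero pairs
        return ConnectivityReport(
            min_spl=float(sentinel),
            avg_spl=float(sentinel),
            disconnected_candidates=float(disconnected),
            pair_count=0,
            sentinel=sentinel,
        )
    return ConnectivityReport(
        min_spl=min(contributions),
        avg_spl=float(np.mean(contributions)),
        disconnected_candidates=float(disconnected),
        pair_count=len(contributions),
        sentinel=sentinel,
    )


def _mean_report(reports: list[ConnectivityReport], sentinel: int) -> ConnectivityReport:
    return ConnectivityReport(
        min_spl=float(np.mean([r.min_spl for r in reports])),
        avg_spl=float(np.mean([r.avg_spl for r in reports])),
        disconnected_candidates=float(
            np.mean([r.disconnected_candidates for r in reports])
        ),
        pair_count=float(np.mean([r.pair_count for r in reports])),
        sentinel=sentinel,
    )


def random_baseline(
    store: Interactome,
    query: GeneSetQuery,
    replicates: int = DEFAULT_REPLICATES,
    seed: int | None = None,
    sentinel: int = DEFAULT_SENTINEL,
) -> BaselineTable:
    """Connectivity of size-matched random gene sets, averaged per scheme.

    Random sets are drawn uniformly without replacement from the store's
    full gene universe (isolated genes included; draws may overlap the
    true sets).  One scheme in candidate-only mode; three in two-set mode,
    each drawn independently per replicate.  ``min_spl`` baseline rows are
    means of per-replicate minima.  Reproducible given (seed, replicates).
    """
    query.validate_against(store)
    if replicates < 1:
        raise ValueError("replicates must be positive")
    universe = sorted(store.keys)
    largest = max(len(query.candidates), len(query.targets or ()))
    if len(universe) < largest:
        raise ValueError(
            f"gene universe ({len(universe)}) smaller than set to randomize ({largest})"
        )
    rng = np.random.default_rng(seed)

    def draw(k: int) -> tuple[str, ...]:
        return tuple(rng.choice(universe, size=k, replace=False))

    n_cand = len(query.candidates)
    schemes: dict[str, tuple[ConnectivityReport, ...]] = {}
    if not query.two_set:
        reps = [
            compute_connectivity(
                store, GeneSetQuery(candidates=draw(n_cand)), sentinel
            )
            for _ in range(replicates)
        ]
        schemes[CANDIDATE_ONLY_SCHEME] = tuple(reps)
    else:
        n_targ = len(query.targets)
        makers = {
            "candidate_to_random": lambda: GeneSetQuery(
                candidates=query.candidates, targets=draw(n_targ)
            ),
            "random_to_target": lambda: GeneSetQuery(
                candidates=draw(n_cand), targets=query.targets
            ),
            "random_to_random": lambda: GeneSetQuery(
                candidates=draw(n_cand), targets=draw(n_targ)
            ),
        }
        for name in TWO_SET_SCHEMES:
            schemes[name] = tuple(
                compute_connectivity(store, makers[name](), sentinel)
                for _ in range(replicates)
            )

    rows = {
        name: _mean_report(list(reps), sentinel) for name, reps in schemes.items()
    }
    return BaselineTable(
        rows=rows, replicates=replicates, seed=seed, replicate_reports=schemes
    )
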