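"""Synthetic interactomes, identifier tables and annotation catalogs.

Every module in the package is testable offline: this generator fabricates
edge lists, three-namespace ID tables and GMT catalogs in exactly the
dialects the store reads, together with a manifest of planted ground truth
(exact pairwise distances, planted term overlaps, injected duplicate and
self-loop counts) that an independent script can verify against the files.

Fabricated identifiers follow recognizable per-namespace patterns
(``SYM0001`` / ``9000001`` / ``Q900001``) so namespace-confusion bugs
surface immediately.  The same seed always produces byte-identical files.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

__all__ = ["FixtureManifest", "gene_ids", "make_interactome", "make_catalog"]

MODELS = ("erdos_renyi", "preferential_attachment", "path_union")


@dataclass
class FixtureManifest:
    """Ground truth for one generated fixture."""

    seed: int
    generator: str
    params: dict
    n_genes: int
    n_edges: int
    files: dict[str, str] = field(default_factory=dict)
    planted_distances: list[list] = field(default_factory=list)  # [key_a, key_b, hops]
    planted_overlaps: list[dict] = field(default_factory=list)
    injected_duplicates: int = 0
    injected_self_loops: int = 0

    def write(self, path) -> None:
        payload = {k: v for k, v in self.__dict__.items()}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def gene_ids(i: int) -> tuple[str, int, str]:
    """Deterministic (symbol, entrez, uniprot) triple for gene index ``i``."""
    return f"SYM{i:04d}", 9000001 + i, f"Q{900001 + i}"


def _write_id_table(path: Path, n_genes: int) -> None:
    lines = ["symbol\tentrez\tuniprot"]
    for i in range(n_genes):
        sym, ent, uni = gene_ids(i)
        lines.append(f"{sym}\t{ent}\t{uni}")
    path.write_text("\n".join(lines) + "\n")


def _build_graph(n_genes: int, model: str, params: dict, seed: int) -> nx.Graph:
    if model == "erdos_renyi":
        p = params.get("p", 0.1)
        G = nx.gnp_random_graph(n_genes, p, seed=seed)
    elif model == "preferential_attachment":
        m = params.get("m", 2)
        if n_genes <= m:
            raise ValueError(f"preferential_attachment needs n_genes > m ({m})")
        G = nx.barabasi_albert_graph(n_genes, m, seed=seed)
    elif model == "path_union":
        G = nx.empty_graph(n_genes)
        pairs = params.get("pairs", [])
        next_new = n_genes
        for a, b, d in pairs:
            if not (0 <= a < n_genes and 0 <= b < n_genes) or a == b:
                raise ValueError(f"bad planted pair ({a}, {b})")
            if d < 1:
                raise ValueError(f"planted distance must be >= 1, got {d}")
            chain = [a] + list(range(next_new, next_new + d - 1)) + [b]
            next_new += d - 1
            G.add_edges_from(zip(chain, chain[1:]))
        # planted chains use fresh interior nodes, so each distance is exact
    else:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    return G


def make_interactome(
    out_dir,
    n_genes: int,
    model: str = "erdos_renyi",
    params: dict | None = None,
    seed: int = 0,
    n_duplicate_rows: int = 0,
    n_self_loops: int = 0,
) -> FixtureManifest:
    """Generate an edge list + ID table fixture under ``out_dir``.

    Models: ``erdos_renyi`` (param ``p``), ``preferential_attachment``
    (param ``m``), ``path_union`` (param ``pairs``: list of
    ``(i, j, distance)`` planted exactly via fresh intermediate genes).
    ``n_duplicate_rows`` re-emits existing edges (half of them reversed)
    and ``n_self_loops`` appends self-loop rows, exercising the loader's
    cleanup accounting.  Files: ``edges.tsv`` (symbol columns, 'simple'
    dialect), ``id_table.tsv``, ``manifest.json``.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    params = dict(params or {})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    G = _build_graph(n_genes, model, params, seed)
    total_genes = G.number_of_nodes()

    edge_rows: list[tuple[int, int]] = sorted(
        (min(a, b), max(a, b)) for a, b in G.edges()
    )
    rng = random.Random(seed)
    extra_rows: list[tuple[int, int]] = []
    if n_duplicate_rows:
        if not edge_rows:
            raise ValueError("cannot inject duplicates into an empty edge set")
        for j in range(n_duplicate_rows):
            a, b = rng.choice(edge_rows)
            extra_rows.append((a, b) if j % 2 == 0 else (b, a))
    for _ in range(n_self_loops):
        g = rng.randrange(total_genes)
        extra_rows.append((g, g))
    all_rows = edge_rows + extra_rows
    rng.shuffle(all_rows)

    sym = {i: gene_ids(i)[0] for i in range(total_genes)}
    edge_path = out_dir / "edges.tsv"
    with open(edge_path, "w") as fh:
        fh.write("# synthetic interactome fixture\n")
        for a, b in all_rows:
            fh.write(f"{sym[a]}\t{sym[b]}\n")
    id_path = out_dir / "id_table.tsv"
    _write_id_table(id_path, total_genes)

    manifest = FixtureManifest(
        seed=seed,
        generator=model,
        params=params,
        n_genes=total_genes,
        n_edges=len(edge_rows),
        files={"edges": str(edge_path), "id_table": str(id_path)},
        planted_distances=[
            [sym[a], sym[b], d] for a, b, d in params.get("pairs", [])
        ],
        injected_duplicates=n_duplicate_rows,
        injected_self_loops=n_self_loops,
    )
    manifest.write(out_dir / "manifest.json")
    return manifest


def make_catalog(
    path,
    universe: list[str],
    n_terms: int,
    overlap_spec: list[tuple[int, int]] | None = None,
    against: list[str] | None = None,
    seed: int = 0,
) -> FixtureManifest:
    """Generate a GMT catalog with exactly planted overlaps.

    ``overlap_spec`` is a list of ``(term_size, overlap)`` pairs: each
    planted term draws ``overlap`` genes from ``against`` (the named gene
    set enrichment will later be tested against) and ``term_size - overlap``
    genes from the rest of the universe, so its contingency table is known
    in closed form.  Remaining terms (up to ``n_terms``) are uniform random
    subsets.  Genes are written as symbols (resolvable by the store).
    """
    path = Path(path)
    universe = list(universe)
    against = list(against or [])
    overlap_spec = list(overlap_spec or [])
    if len(overlap_spec) > n_terms:
        raise ValueError("more planted terms than n_terms")
    against_set = set(against)
    outside = [g for g in universe if g not in against_set]
    rng = random.Random(seed)

    lines: list[str] = []
    planted: list[dict] = []
    for idx, (size, overlap) in enumerate(overlap_spec):
        if overlap > len(against) or size - overlap > len(outside) or overlap > size:
            raise ValueError(
                f"infeasible overlap spec ({size}, {overlap}) for universe "
                f"{len(universe)} / against {len(against)}"
            )
        inside = rng.sample(against, overlap)
        rest = rng.sample(outside, size - overlap)
        genes = sorted(inside + rest)
        term = f"PLANTED_{idx:03d}"
        lines.append("\t".join([term, f"planted overlap {overlap}/{size}"] + genes))
        planted.append({"term": term, "size": size, "overlap": overlap})
    for idx in range(n_terms - len(overlap_spec)):
        size = rng.randint(1, max(1, min(len(universe), 20)))
        genes = sorted(rng.sample(universe, size))
        lines.append("\t".join([f"RANDOM_{idx:03d}", "random term"] + genes))
    path.write_text("\n".join(lines) + "\n")

    manifest = FixtureManifest(
        seed=seed,
        generator="catalog",
        params={"n_terms": n_terms, "universe_size": len(universe)},
        n_genes=len(universe),
        n_edges=0,
        files={"gmt": str(path)},
        planted_overlaps=planted,
    )
    return manifest
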