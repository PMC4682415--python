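from __future__ import annotations

import pytest

from seednet.build import GeneSetQuery
from seednet.store import GeneRecord, Interactome


def store_from(edges, extra_nodes=(), with_ids=False):
    """Build an in-memory store from symbol edge pairs (keys = upper-cased
    symbols).  ``with_ids`` fabricates Entrez/UniProt IDs as well."""
    names = sorted({n for e in edges for n in e} | set(extra_nodes))
    records = []
    for i, name in enumerate(names):
        if with_ids:
            records.append(
                GeneRecord(
                    key=name.upper(),
                    symbol=name,
                    entrez=1000 + i,
                    uniprot=f"P{10000 + i}",
                )
            )
        else:
            records.append(GeneRecord(key=name.upper(), symbol=name))
    return Interactome(records, edges=[(a.upper(), b.upper()) for a, b in edges])


def query(candidates, targets=None):
    return GeneSetQuery(
        candidates=tuple(candidates),
        targets=None if targets is None else tuple(targets),
    )


@pytest.fixture
def path_store():
    """Path graph A-B-C-D-E."""
    return store_from([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])


@pytest.fixture
def diamond_store():
    """Diamond A-B-D, A-C-D (two co-minimal length-2 paths A..D)."""
    return store_from([("A", "B"), ("B", "D"), ("A", "C"), ("C", "D")])


@pytest.fixture
def two_component_store():
    """Two disjoint components {A-B} and {C-D} plus isolated E."""
    return store_from([("A", "B"), ("C", "D")], extra_nodes=["E"])
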