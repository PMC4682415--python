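"""Interactome store: loading, canonicalization, resolution, catalogs."""

from __future__ import annotations

import pytest

from seednet.fixtures import make_interactome
from seednet.store import (
    DialectError,
    EdgeListDialect,
    EmptyQueryError,
    GeneRecord,
    Interactome,
    StoreError,
    load_catalog,
    load_interactome,
    resolve_genes,
)

from conftest import store_from


def write(path, text):
    path.write_text(text)
    return path


@pytest.fixture
def abc_id_table(tmp_path):
    return write(
        tmp_path / "ids.tsv",
        "symbol\tentrez\tuniprot\nA\t1\tP1\nB\t2\tP2\nC\t3\tP3\n",
    )


class TestLoadInteractome:
    def test_self_loops_dropped_and_duplicates_collapsed(self, tmp_path, abc_id_table):
        edges = write(tmp_path / "e.tsv", "A\tB\nB\tA\nC\tC\n")
        store = load_interactome(edges, abc_id_table)
        assert store.edges == {("A", "B")}
        assert len(store) == 3  # C stays as an isolated gene
        rep = store.load_report
        assert rep.dropped["duplicate"] == 1
        assert rep.dropped["self_loop"] == 1
        assert rep.rows_read == 3 and rep.rows_kept == 1

    def test_interaction_type_code_filter(self, tmp_path, abc_id_table):
        edges = write(tmp_path / "e.tsv", "A\tB\tMI:0417\nA\tC\tMI:0915\n")
        store = load_interactome(
            edges,
            abc_id_table,
            interaction_type_filter={"0417"},
            dialect="simple-typed",
        )
        assert store.edges == {("A", "B")}
        assert store.load_report.dropped["type_filtered"] == 1

    def test_filter_ignored_without_type_column_dialect(self, tmp_path, abc_id_table):
        edges = write(tmp_path / "e.tsv", "A\tB\nA\tC\n")
        store = load_interactome(edges, abc_id_table, interaction_type_filter={"0417"})
        assert len(store.edges) == 2

    def test_comments_and_blank_lines_ignored(self, tmp_path, abc_id_table):
        edges = write(tmp_path / "e.tsv", "# hdr\n\nA\tB\n")
        store = load_interactome(edges, abc_id_table)
        assert store.edges == {("A", "B")}

    def test_unresolvable_rows_dropped_not_fatal(self, tmp_path, abc_id_table):
        edges = write(tmp_path / "e.tsv", "A\tB\nA\tNOPE\n")
        store = load_interactome(edges, abc_id_table)
        assert store.edges == {("A", "B")}
        assert store.load_report.dropped["unresolved"] == 1

    def test_no_resolvable_rows_is_an_error(self, tmp_path, abc_id_table):
        edges = write(tmp_path / "e.tsv", "X\tY\n")
        with pytest.raises(StoreError, match="no resolvable"):
            load_interactome(edges, abc_id_table)

    def test_missing_file_raises(self, tmp_path, abc_id_table):
        with pytest.raises(StoreError, match="cannot read"):
            load_interactome(tmp_path / "absent.tsv", abc_id_table)

    def test_malformed_header_for_declared_dialect(self, tmp_path, abc_id_table):
        edges = write(tmp_path / "e.tsv", "a\tb\nA\tB\n")
        dialect = EdgeListDialect(1, 2, 11, has_header=True)
        with pytest.raises(DialectError, match="header"):
            load_interactome(edges, abc_id_table, dialect=dialect)

    def test_hprd_flat_dialect_reads_columns_0_and_3(self, tmp_path, abc_id_table):
        edges = write(tmp_path / "e.tsv", "A\th1\tr1\tB\th2\tr2\texp\t123\n")
        store = load_interactome(edges, abc_id_table, dialect="hprd-flat")
        assert store.edges == {("A", "B")}

    def test_dedup_matches_brute_force_on_generated_fixture(self, tmp_path):
        """200-gene fixture with injected duplicates and self-loops: loader
        counts equal an independent set-based dedupe over the raw rows."""
        man = make_interactome(
            tmp_path,
            n_genes=200,
            model="erdos_renyi",
            params={"p": 0.02},
            seed=7,
            n_duplicate_rows=10,
            n_self_loops=5,
        )
        # independent pass over the raw file
        raw = [
            line.split("\t")
            for line in (tmp_path / "edges.tsv").read_text().splitlines()
            if line and not line.startswith("#")
        ]
        uniq = {frozenset((a, b)) for a, b in raw if a != b}
        n_self = sum(1 for a, b in raw if a == b)
        store = load_interactome(tmp_path / "edges.tsv", tmp_path / "id_table.tsv")
        assert len(store.edges) == len(uniq) == man.n_edges
        assert len(store) == man.n_genes
        assert store.load_report.dropped["self_loop"] == n_self == 5
        assert store.load_report.dropped["duplicate"] == len(raw) - n_self - len(uniq)


class TestResolveGenes:
    def test_case_insensitive_symbol_match(self):
        store = store_from([("MSX1", "MSX2")])
        res = resolve_genes(["msx1"], store)
        assert res.resolved == ("MSX1",)
        assert res.rejected == ()

    def test_duplicates_collapse_and_unknown_reported(self):
        store = store_from([("MSX1", "MSX2")])
        res = resolve_genes(["MSX1", "MSX1", "NOPE"], store)
        assert res.resolved == ("MSX1",)
        assert res.rejected == (("NOPE", "unknown"),)

    def test_namespace_precedence_symbol_first_then_configurable(self):
        """A token that is an Entrez ID of one gene and a symbol of another
        resolves by namespace precedence."""
        records = [
            GeneRecord(key="X", symbol="GENEX", entrez=7088),
            GeneRecord(key="Y", symbol="7088"),
        ]
        store = Interactome(records)
        assert resolve_genes(["7088"], store).resolved == ("Y",)
        flipped = Interactome(records, precedence=("entrez", "symbol", "uniprot"))
        assert resolve_genes(["7088"], flipped).resolved == ("X",)

    def test_entrez_and_uniprot_namespaces(self):
        records = [GeneRecord(key="A", symbol="A", entrez=42, uniprot="P12345")]
        store = Interactome(records)
        for token in ["42", "p12345", "P12345-2"]:
            assert resolve_genes([token], store).resolved == ("A",)

    def test_all_rejected_is_distinct_empty_query_error(self):
        store = store_from([("A", "B")])
        with pytest.raises(EmptyQueryError):
            resolve_genes(["nope1", "nope2"], store)

    def test_ambiguous_value_rejected_with_reason(self):
        records = [
            GeneRecord(key="G1", symbol="DUP", entrez=1),
            GeneRecord(key="G2", symbol="DUP", entrez=2),
        ]
        store = Interactome(records)
        res = store.resolve(["DUP", "1"], raise_on_empty=False)
        assert ("DUP", "ambiguous") in res.rejected
        assert res.resolved == ("G1",)

    def test_resolution_is_a_fixed_point(self, path_store):
        res = resolve_genes(["a", "E", "c"], path_store)
        again = resolve_genes(list(res.resolved), path_store)
        assert again.resolved == res.resolved and again.rejected == ()


class TestLoadCatalog:
    def test_one_term_both_genes_kept(self, tmp_path, abc_id_table):
        edges = write(tmp_path / "e.tsv", "A\tB\n")
        store = load_interactome(edges, abc_id_table)
        gmt = write(tmp_path / "c.gmt", "T1\tdesc\tA\tB\n")
        cat = load_catalog(gmt, "pathway", store)
        assert cat.terms == {"T1": frozenset({"A", "B"})}

    def test_unknown_tokens_dropped_and_counted(self, tmp_path, abc_id_table):
        edges = write(tmp_path / "e.tsv", "A\tB\n")
        store = load_interactome(edges, abc_id_table)
        gmt = write(tmp_path / "c.gmt", "T1\tdesc\tA\tZZZ\n")
        cat = load_catalog(gmt, "disease", store)
        assert cat.terms == {"T1": frozenset({"A"})}
        assert cat.load_report.dropped["unknown_gene_token"] == 1

    def test_emptied_terms_removed_and_zero_terms_fatal(self, tmp_path, abc_id_table):
        edges = write(tmp_path / "e.tsv", "A\tB\n")
        store = load_interactome(edges, abc_id_table)
        gmt = write(tmp_path / "c.gmt", "T1\tdesc\tA\nT2\tdesc\tZZZ\n")
        cat = load_catalog(gmt, "drug", store)
        assert set(cat.terms) == {"T1"}
        bad = write(tmp_path / "bad.gmt", "T\tdesc\tZZZ\n")
        with pytest.raises(StoreError, match="zero surviving"):
            load_catalog(bad, "gwas", store)

    def test_surviving_counts_match_intersection_oracle(self, tmp_path):
        """50-term generated catalog with planted unknowns: per-term counts
        equal a line-by-line set intersection against the store."""
        from seednet.fixtures import gene_ids, make_catalog

        man = make_interactome(tmp_path, n_genes=60, params={"p": 0.05}, seed=3)
        store = load_interactome(tmp_path / "edges.tsv", tmp_path / "id_table.tsv")
        symbols = [gene_ids(i)[0] for i in range(man.n_genes)]
        universe = symbols + [f"FAKE{i}" for i in range(10)]  # planted unknowns
        gmt = tmp_path / "c.gmt"
        make_catalog(gmt, universe, n_terms=50, seed=11)
        cat = load_catalog(gmt, "pathway", store)
        known = set(symbols)
        for line in gmt.read_text().splitlines():
            term, _desc, *genes = line.split("\t")
            survive = set(genes) & known
            if survive:
                assert len(cat.terms[term]) == len(survive)
            else:
                assert term not in cat.terms


class TestProperties:
    def test_edge_list_round_trip(self, tmp_path):
        make_interactome(tmp_path, n_genes=40, params={"p": 0.08}, seed=5)
        store = load_interactome(tmp_path / "edges.tsv", tmp_path / "id_table.tsv")
        out = tmp_path / "roundtrip.tsv"
        store.write_edge_list(out)
        again = load_interactome(out, tmp_path / "id_table.tsv")
        assert again.keys == store.keys
        assert again.edges == store.edges

    def test_load_is_idempotent(self, tmp_path):
        make_interactome(tmp_path, n_genes=30, params={"p": 0.1}, seed=9)
        a = load_interactome(tmp_path / "edges.tsv", tmp_path / "id_table.tsv")
        b = load_interactome(tmp_path / "edges.tsv", tmp_path / "id_table.tsv")
        assert a.keys == b.keys and a.edges == b.edges
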