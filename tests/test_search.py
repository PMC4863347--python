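"""Search semantics: db filters, MeSH expansion and filtering, sorting,
pagination and the evaluation statistics."""

from decimal import Decimal

import pytest
from hypothesis import given, strategies as st

from mirkg.annotate import (
    SOURCE_CONFIGS,
    GeneDataRow,
    GeneRegistry,
    MirnaDictionary,
    Publication,
    annotate_prediction_rows,
    declare_gene_class,
)
from mirkg.ontology import OntologyError, Term, build_ontology
from mirkg.search import (
    EvidenceSet,
    ResultRow,
    ResultTable,
    SearchError,
    SearchRequest,
    mesh_expand,
    paginate,
    percent_reduction,
    precision_recall,
    search,
    sort_rows,
)
from mirkg.store import TripleStore
from mirkg.triples import InstanceMinter
from mirkg.vocab import OBO_BASE

MIRNA_NAME = "hsa-miR-125b-5p"
MIRNA_CURIE = "NCRO_0100001"
M1, M2, M3 = "MESH_0000001", "MESH_0000002", "MESH_0000003"


def build_graph():
    """miRNA term plus MeSH chain M3 is_a M2 is_a M1."""
    return build_ontology(
        [
            Term(MIRNA_CURIE, MIRNA_NAME, frozenset(), "miRNA"),
            Term(M1, "mesh root", frozenset(), "MeSH"),
            Term(M2, "drug resistance", frozenset([M1]), "MeSH"),
            Term(M3, "multidrug resistance", frozenset([M2]), "MeSH"),
        ]
    )


def build_store(per_source: dict[str, dict[str, str]]) -> TripleStore:
    """per_source: source name -> {gene_id: score string}."""
    dictionary = MirnaDictionary()
    dictionary[MIRNA_NAME] = OBO_BASE + MIRNA_CURIE
    minter = InstanceMinter()
    genes = GeneRegistry()
    triples = []
    declared = set()
    for source in sorted(per_source):
        rows = [
            GeneDataRow(MIRNA_NAME, gid, f"SYM_{gid}", score)
            for gid, score in sorted(per_source[source].items())
        ]
        ts, _ = annotate_prediction_rows(
            rows, dictionary, minter, SOURCE_CONFIGS[source], genes
        )
        triples += ts
        for row in rows:
            if row.gene_id not in declared:
                declared.add(row.gene_id)
                triples += declare_gene_class(row.gene_id, row.gene_symbol, genes)
    return TripleStore(triples)


def run(store, req, pubs=(), gos=(), graph=None, sources=None):
    return search(
        store,
        EvidenceSet(publications=list(pubs), go_annotations=list(gos)),
        graph or build_graph(),
        req,
        sources,
    )


class TestMeshExpand:
    def test_exact_is_singleton(self):
        assert mesh_expand(build_graph(), M2, "exact") == {M2}

    def test_broader_at_root_is_just_root(self):
        assert mesh_expand(build_graph(), M1, "broader") == {M1}

    def test_narrower_from_root_covers_chain(self):
        assert mesh_expand(build_graph(), M1, "narrower") == {M1, M2, M3}

    def test_combined_mode(self):
        assert mesh_expand(build_graph(), M2, "exact+broader+narrower") == {M1, M2, M3}

    def test_unknown_term_errors(self):
        with pytest.raises(OntologyError):
            mesh_expand(build_graph(), "MESH_0099999", "exact")

    def test_exact_subset_of_expansions(self):
        graph = build_graph()
        for term in (M1, M2, M3):
            exact = mesh_expand(graph, term, "exact")
            assert exact <= mesh_expand(graph, term, "broader")
            assert exact <= mesh_expand(graph, term, "narrower")


class TestDbFilters:
    PER_SOURCE = {
        "miRDB": {"1": "90", "2": "80", "3": "70"},
        "TargetScan": {"2": "-0.5", "3": "-0.4", "4": "-0.3"},
        "miRanda": {},
    }

    def test_any_is_union(self):
        table = run(build_store(self.PER_SOURCE), SearchRequest(mirna=MIRNA_NAME))
        assert table.total_distinct_targets == 4

    def test_all_with_empty_source_is_empty(self):
        table = run(
            build_store(self.PER_SOURCE),
            SearchRequest(mirna=MIRNA_NAME, db_filter="all"),
        )
        assert table.total_distinct_targets == 0

    def test_all_over_covering_sources_is_intersection(self):
        configs = [SOURCE_CONFIGS["miRDB"], SOURCE_CONFIGS["TargetScan"]]
        table = run(
            build_store(self.PER_SOURCE),
            SearchRequest(mirna=MIRNA_NAME, db_filter="all"),
            sources=configs,
        )
        assert {r.gene_id for r in table.rows} == {"2", "3"}

    def test_specific_source(self):
        table = run(
            build_store(self.PER_SOURCE),
            SearchRequest(
                mirna=MIRNA_NAME, db_filter="specific", specific_source="miRDB"
            ),
        )
        assert table.total_distinct_targets == 3

    def test_size_ordering_any_specific_all(self):
        store = build_store(self.PER_SOURCE)
        any_n = run(store, SearchRequest(mirna=MIRNA_NAME)).total_distinct_targets
        all_n = run(
            store, SearchRequest(mirna=MIRNA_NAME, db_filter="all")
        ).total_distinct_targets
        for s in self.PER_SOURCE:
            spec_n = run(
                store,
                SearchRequest(mirna=MIRNA_NAME, db_filter="specific", specific_source=s),
            ).total_distinct_targets
            assert any_n >= spec_n >= all_n

    def test_unknown_mirna_gives_warning_not_error(self):
        table = run(build_store(self.PER_SOURCE), SearchRequest(mirna="no-such-mir"))
        assert table.total_distinct_targets == 0
        assert table.warning

    def test_scores_attached_per_source(self):
        table = run(build_store(self.PER_SOURCE), SearchRequest(mirna=MIRNA_NAME))
        by_id = {r.gene_id: r for r in table.rows}
        assert by_id["2"].predicted_by == {"miRDB", "TargetScan"}
        assert by_id["2"].scores["miRDB"] == Decimal(80)
        assert by_id["2"].scores["TargetScan"] == Decimal("-0.5")
        assert set(by_id["2"].scores) <= by_id["2"].predicted_by


def make_pub(pmid, gene, mesh=(), mirna=MIRNA_CURIE):
    return Publication(
        pmid=pmid,
        mesh_terms=frozenset(mesh),
        gene_ids=frozenset([gene]),
        mirna_ids=frozenset([mirna] if mirna else []),
    )


@pytest.fixture(scope="module")
def store():
    return build_store({"miRDB": {"1": "90", "2": "80"}})


class TestPublicationAttachment:

    def test_pub_needs_gene_and_mirna_link(self, store):
        pubs = [
            make_pub(101, "1", [M2]),
            make_pub(102, "1", [M2], mirna="NCRO_0999999"),  # other miRNA
            make_pub(103, "9", [M2]),  # other gene
        ]
        table = run(store, SearchRequest(mirna=MIRNA_NAME), pubs=pubs)
        by_id = {r.gene_id: r for r in table.rows}
        assert by_id["1"].publications == {101}
        assert by_id["2"].publications == set()

    def test_mesh_filter_never_grows_publication_sets(self, store):
        pubs = [make_pub(101, "1", [M2]), make_pub(102, "1", [M1])]
        unfiltered = run(store, SearchRequest(mirna=MIRNA_NAME), pubs=pubs)
        filtered = run(
            store, SearchRequest(mirna=MIRNA_NAME, mesh_term=M2), pubs=pubs
        )
        un = {r.gene_id: r.publications for r in unfiltered.rows}
        fi = {r.gene_id: r.publications for r in filtered.rows}
        for gid in fi:
            assert fi[gid] <= un[gid]
        assert fi["1"] == {101}

    def test_broader_mode_admits_ancestor_term_pubs(self, store):
        pubs = [make_pub(101, "1", [M1])]  # carries only the broader term
        exact = run(store, SearchRequest(mirna=MIRNA_NAME, mesh_term=M2), pubs=pubs)
        broader = run(
            store,
            SearchRequest(mirna=MIRNA_NAME, mesh_term=M2, mesh_mode="broader"),
            pubs=pubs,
        )
        assert all(r.publications == set() for r in exact.rows)
        by_id = {r.gene_id: r.publications for r in broader.rows}
        assert by_id["1"] == {101}

    def test_evidence_filter_partitions_rows(self, store):
        pubs = [make_pub(101, "1", [M2])]
        with_pubs = run(
            store,
            SearchRequest(mirna=MIRNA_NAME, evidence_filter="with_publications"),
            pubs=pubs,
        )
        without = run(
            store,
            SearchRequest(mirna=MIRNA_NAME, evidence_filter="without_publications"),
            pubs=pubs,
        )
        assert {r.gene_id for r in with_pubs.rows} == {"1"}
        assert {r.gene_id for r in without.rows} == {"2"}
        assert with_pubs.total_distinct_targets == 1


def row(gid, symbol, **scores):
    return ResultRow(
        gene_id=gid,
        gene_symbol=symbol,
        predicted_by=set(scores),
        scores={k: Decimal(str(v)) for k, v in scores.items()},
    )


class TestSortRows:
    def test_descending_by_score(self):
        table = ResultTable(rows=[row("1", "A", miRDB=90), row("2", "B", miRDB=100)])
        assert [r.gene_symbol for r in sort_rows(table, "miRDB").rows] == ["B", "A"]

    def test_tie_breaks_by_symbol(self):
        table = ResultTable(rows=[row("2", "B", miRDB=50), row("1", "A", miRDB=50)])
        assert [r.gene_symbol for r in sort_rows(table, "miRDB").rows] == ["A", "B"]

    def test_scoreless_rows_trail_in_symbol_order(self):
        table = ResultTable(
            rows=[row("1", "Z"), row("2", "A", miRDB=10), row("3", "B")]
        )
        assert [r.gene_symbol for r in sort_rows(table, "miRDB").rows] == ["A", "B", "Z"]

    def test_matches_oracle_key_on_mixed_fixture(self):
        import random

        rng = random.Random(5)
        rows = []
        for i in range(10):
            if rng.random() < 0.6:
                rows.append(row(str(i), f"S{i}", miRDB=rng.randint(0, 100)))
            else:
                rows.append(row(str(i), f"S{i}"))
        got = [r.gene_id for r in sort_rows(ResultTable(rows=rows), "miRDB").rows]
        scored = sorted(
            (r for r in rows if "miRDB" in r.scores),
            key=lambda r: (-r.scores["miRDB"], r.gene_symbol),
        )
        unscored = sorted(
            (r for r in rows if "miRDB" not in r.scores), key=lambda r: r.gene_symbol
        )
        assert got == [r.gene_id for r in scored + unscored]


class TestPaginate:
    def test_page_sizes_4_4_2(self):
        table = ResultTable(rows=[row(str(i), f"S{i}") for i in range(10)])
        sizes = [len(paginate(table, p, 4).rows) for p in (1, 2, 3)]
        assert sizes == [4, 4, 2]

    def test_page_beyond_range_is_empty(self):
        table = ResultTable(rows=[row(str(i), f"S{i}") for i in range(10)])
        assert paginate(table, 4, 4).rows == []

    @given(st.integers(1, 7), st.integers(0, 25))
    def test_concatenating_pages_reproduces_order(self, k, n):
        table = ResultTable(rows=[row(str(i), f"S{i}") for i in range(n)])
        seen = []
        page = 1
        while True:
            chunk = paginate(table, page, k).rows
            if not chunk:
                break
            seen += chunk
            page += 1
        assert [r.gene_id for r in seen] == [r.gene_id for r in table.rows]

    def test_invalid_page_errors(self):
        with pytest.raises(SearchError):
            paginate(ResultTable(), 0, 5)


class TestPercentReduction:
    @pytest.mark.parametrize(
        "before,after,expected",
        [
            (50, 16, 68),
            (13, 2, 85),
            (31, 3, 90),
            (43, 4, 91),
            (12, 1, 92),
            (452, 31, 93),
            (266, 11, 96),
            (118, 4, 97),
            (91, 3, 97),
            (41, 1, 98),
        ],
    )
    def test_published_reduction_pairs(self, before, after, expected):
        assert percent_reduction(before, after) == expected

    def test_no_reduction_is_zero(self):
        assert percent_reduction(17, 17) == 0

    def test_rounds_half_away_from_zero(self):
        assert percent_reduction(200, 199) == 1  # 0.5 % -> 1

    @pytest.mark.parametrize("before,after", [(0, 0), (5, 6), (5, -1)])
    def test_invalid_inputs(self, before, after):
        with pytest.raises(SearchError):
            percent_reduction(before, after)


class TestPrecisionRecall:
    def test_term_filtered_set_has_precision_one(self):
        pubs = [make_pub(i, "1", [M2]) for i in range(1, 8)]
        pr = precision_recall(pubs, {M2}, gold=set())
        assert pr.precision == 1.0 and pr.recall is None

    def test_recall_fraction(self):
        pubs = [make_pub(i, "1", [M2]) for i in range(1, 8)]
        pr = precision_recall(pubs, {M2}, gold=set(range(1, 11)))
        assert pr.recall == pytest.approx(0.7)

    def test_returned_equals_gold(self):
        pubs = [make_pub(i, "1", [M2]) for i in range(1, 6)]
        pr = precision_recall(pubs, {M2}, gold={1, 2, 3, 4, 5})
        assert (pr.precision, pr.recall) == (1.0, 1.0)

    def test_empty_returned_flags_precision(self):
        pr = precision_recall([], {M2}, gold={1})
        assert pr.precision is None and pr.recall == 0.0

    def test_empty_gold_flags_recall(self):
        pr = precision_recall([], {M2}, gold=set())
        assert pr.precision is None and pr.recall is None


class TestSetSemanticsProperty:
    @given(
        st.dictionaries(
            st.sampled_from(["miRDB", "TargetScan", "miRanda"]),
            st.dictionaries(
                st.integers(1, 12).map(str), st.integers(1, 99).map(str), max_size=8
            ),
            min_size=1,
        )
    )
    def test_any_is_union_all_is_intersection(self, per_source):
        store = build_store(per_source)
        configs = [SOURCE_CONFIGS[s] for s in sorted(per_source)]
        any_table = run(store, SearchRequest(mirna=MIRNA_NAME), sources=configs)
        all_table = run(
            store, SearchRequest(mirna=MIRNA_NAME, db_filter="all"), sources=configs
        )
        union = set().union(*(set(m) for m in per_source.values()))
        inter = set.intersection(*(set(m) for m in per_source.values()))
        assert {r.gene_id for r in any_table.rows} == union
        assert {r.gene_id for r in all_table.rows} == inter
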