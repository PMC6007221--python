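"""Knowledge-assembly model: parsing, round trips, induction, summaries."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comorbnet import (
    BioEntity,
    CausalRelation,
    KnowledgeAssembly,
    induce_subgraph,
    parse_bel_subset,
    read_nodelink,
    serialize_bel,
    summarize_subgraphs,
    write_nodelink,
)
from comorbnet.bel import (
    parse_bel_subset_with_report,
    parse_term,
    relabel_entities,
)
from comorbnet.errors import (
    BELParseError,
    MissingCitationError,
    SchemaValidationError,
    UnknownLabelError,
)
from comorbnet.reference import (
    DISCREPANT_CONDITIONS,
    EPILEPSY_N_GENES,
    comorbidity_reference,
)

from conftest import CITE, make_assembly, process, protein

# ---------------------------------------------------------------------------
# hypothesis strategy for random assemblies
# ---------------------------------------------------------------------------

_entities = st.builds(
    BioEntity,
    function=st.sampled_from(["protein", "gene", "rna", "abundance",
                              "bioprocess", "pathology", "complex"]),
    namespace=st.sampled_from(["HGNC", "CHEBI", "GO", "MESH"]),
    name=st.one_of(
        st.sampled_from(["SCN1A", "GABRA1", "ADK", "adenosine",
                         "neuronal action potential", 'with "quotes"']),
        st.text(
            st.characters(whitelist_categories=("Lu", "Ll", "Nd"),
                          whitelist_characters=" -_."),
            min_size=1, max_size=12).map(str.strip).filter(bool),
    ),
)

_relations = st.builds(
    CausalRelation,
    subject=_entities,
    relation=st.sampled_from(sorted(
        {"increases", "directly_increases", "decreases",
         "directly_decreases", "regulates", "association",
         "positive_correlation", "negative_correlation"})),
    object=_entities,
    citation=st.tuples(st.sampled_from(["PubMed", "DOI"]),
                       st.sampled_from(["1", "22", "333"])),
    evidence=st.one_of(st.none(),
                       st.sampled_from(["some evidence", "another line"])),
    subgraphs=st.frozensets(
        st.sampled_from(["Gaba subgraph", "Mapk-erk", "Calcium dependent"]),
        max_size=2),
)

assemblies = st.builds(
    KnowledgeAssembly,
    entities=st.frozensets(_entities, max_size=4),
    relations=st.lists(_relations, max_size=10).map(tuple),
    subgraph_inventory=st.frozensets(
        st.sampled_from(["Gaba subgraph", "Unused label"]), max_size=2),
)


class TestParsing:
    def test_two_line_script(self):
        asm = parse_bel_subset(
            'SET Citation = {"PubMed", "11"}\n'
            'p(HGNC:SCN1A) decreases bp(GO:"neuronal action potential")\n')
        assert len(asm.entities) == 2
        assert len(asm.relations) == 1
        rel = asm.relations[0]
        assert rel.citation == ("PubMed", "11")
        assert rel.object.name == "neuronal action potential"

    def test_subgraph_annotation_carried(self, gaba_script):
        asm = parse_bel_subset(gaba_script)
        assert asm.relations[0].subgraphs == {"Gaba subgraph"}
        assert asm.relations[2].subgraphs == {
            "Gaba subgraph", "Adenosine signaling subgraph"}
        assert asm.relations[3].subgraphs == frozenset()
        assert asm.relations[0].evidence is not None

    def test_statement_before_citation(self):
        with pytest.raises(MissingCitationError) as err:
            parse_bel_subset("p(HGNC:A) increases p(HGNC:B)\n")
        assert err.value.line_number == 1

    def test_unknown_relation_keyword(self):
        with pytest.raises(BELParseError) as err:
            parse_bel_subset(
                'SET Citation = {"PubMed", "1"}\n'
                "p(HGNC:A) frobnicates p(HGNC:B)\n")
        assert err.value.line_number == 2

    def test_nested_term_rejected(self):
        with pytest.raises(BELParseError):
            parse_bel_subset(
                'SET Citation = {"PubMed", "1"}\n'
                "p(HGNC:A, pmod(P)) increases p(HGNC:B)\n")

    def test_lenient_mode_counts_skipped(self):
        text = (
            'SET Citation = {"PubMed", "1"}\n'
            "p(HGNC:A, pmod(P)) increases p(HGNC:B)\n"
            "p(HGNC:A) increases p(HGNC:B)\n"
            "complex(p(HGNC:A), p(HGNC:B)) increases p(HGNC:C)\n")
        asm, report = parse_bel_subset_with_report(text, lenient=True)
        assert len(asm.relations) == 1
        assert report.n_skipped == 2
        assert [ln for ln, _ in report.skipped_lines] == [2, 4]

    def test_arrow_shorthand_and_three_field_citation(self):
        asm = parse_bel_subset(
            'SET Citation = {"PubMed", "Some title", "77"}\n'
            "p(HGNC:A) -| p(HGNC:B)\n")
        assert asm.relations[0].relation == "decreases"
        assert asm.relations[0].citation == ("PubMed", "77")

    def test_parse_term_helper(self):
        e = parse_term('bp(GO:"action potential")')
        assert e == BioEntity("bioprocess", "GO", "action potential")
        with pytest.raises(BELParseError):
            parse_term("p(HGNC)")


class TestRoundTrip:
    @given(assemblies)
    @settings(max_examples=60, deadline=None)
    def test_serialize_then_parse_is_isomorphic(self, asm):
        again = parse_bel_subset(serialize_bel(asm))
        # BEL script has no isolated-entity statement, so compare relations
        # and inventory; endpoint entities follow from the relations
        from collections import Counter
        assert Counter(again.relations) == Counter(asm.relations)
        assert again.subgraph_inventory == asm.subgraph_inventory

    @given(assemblies)
    @settings(max_examples=60, deadline=None)
    def test_nodelink_round_trip(self, tmp_path_factory, asm):
        path = tmp_path_factory.mktemp("nl") / "asm.json"
        write_nodelink(asm, path)
        assert read_nodelink(path).isomorphic_to(asm)

    def test_empty_assembly_round_trips(self, tmp_path):
        empty = KnowledgeAssembly(frozenset(), ())
        path = tmp_path / "empty.json"
        write_nodelink(empty, path)
        assert read_nodelink(path).isomorphic_to(empty)
        assert parse_bel_subset(serialize_bel(empty)).isomorphic_to(empty)

    def test_nodelink_schema_violation_names_field(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(
            '{"entities": [], "relations": [{"subject": '
            '{"function": "protein", "namespace": "HGNC", "name": "A"},'
            '"relation": "increases", "object": {"function": "protein",'
            '"namespace": "HGNC", "name": "B"}, "citation": ["PubMed", ""]}],'
            ' "subgraph_inventory": []}')
        with pytest.raises(SchemaValidationError) as err:
            read_nodelink(path)
        assert "citation" in err.value.field

    def test_fixture_file_counts(self, tmp_path, gaba_script):
        path = tmp_path / "toy.bel"
        path.write_text(gaba_script)
        asm = parse_bel_subset(path.read_text())
        assert len(asm.relations) == 4
        assert len(asm.entities) == 7
        assert asm.subgraph_inventory == {
            "Gaba subgraph", "Adenosine signaling subgraph"}


class TestInduceSubgraph:
    def test_unknown_label_lists_valid(self, gaba_script):
        asm = parse_bel_subset(gaba_script)
        with pytest.raises(UnknownLabelError) as err:
            induce_subgraph(asm, "nope")
        assert "Gaba subgraph" in str(err.value)

    def test_label_with_no_relation_gives_empty_assembly(self):
        asm = KnowledgeAssembly(frozenset(), (),
                                frozenset({"declared only"}))
        induced = induce_subgraph(asm, "declared only")
        assert len(induced.relations) == 0 and len(induced.entities) == 0

    def test_counts_and_endpoints(self, gaba_script):
        asm = parse_bel_subset(gaba_script)
        induced = induce_subgraph(asm, "Gaba subgraph")
        assert len(induced.relations) == 3
        brute = {e for r in induced.relations for e in (r.subject, r.object)}
        assert induced.entities == brute

    @given(assemblies)
    @settings(max_examples=40, deadline=None)
    def test_induced_entities_are_endpoint_union(self, asm):
        for label in asm.subgraph_inventory:
            induced = induce_subgraph(asm, label)
            assert induced.entities == {
                e for r in asm.relations if label in r.subgraphs
                for e in (r.subject, r.object)}


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

class UnionFind:
    """Independent connected-components oracle."""

    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def n_components(self):
        return len({self.find(x) for x in self.parent})


def union_find_components(asm: KnowledgeAssembly) -> int:
    uf = UnionFind(asm.entities)
    for r in asm.relations:
        uf.union(r.subject, r.object)
    return uf.n_components()


class TestSummaries:
    def test_single_relation(self):
        asm = make_assembly([(protein("A"), process("x"))], label="L")
        rows = summarize_subgraphs(asm)
        assert rows[0] == ("L", 2, 1, 1, 1)
        assert rows[-1].label == "Total"
        assert rows[-1][1:] == (2, 1, 1, 1)

    def test_two_disjoint_relations_two_components(self):
        asm = make_assembly(
            [(protein("A"), protein("B")), (protein("C"), protein("D"))],
            label="L")
        rows = summarize_subgraphs(asm)
        assert rows[0].n_connected_components == 2

    def test_total_citations_deduplicated(self):
        a, b, c = protein("A"), protein("B"), protein("C")
        r1 = CausalRelation(a, "increases", b, CITE,
                            subgraphs=frozenset({"L1"}))
        r2 = CausalRelation(b, "increases", c, CITE,
                            subgraphs=frozenset({"L2"}))
        asm = KnowledgeAssembly(frozenset(), (r1, r2))
        rows = {s.label: s for s in summarize_subgraphs(asm)}
        per_label_sum = rows["L1"].n_citations + rows["L2"].n_citations
        assert rows["Total"].n_citations == 1 <= per_label_sum

    def test_multi_edges_count_separately(self):
        a, b = protein("A"), protein("B")
        r1 = CausalRelation(a, "increases", b, ("PubMed", "1"))
        r2 = CausalRelation(a, "increases", b, ("PubMed", "2"))
        asm = KnowledgeAssembly(frozenset(), (r1, r2))
        total = summarize_subgraphs(asm)[-1]
        assert total.n_relationships == 2 and total.n_citations == 2

    @given(assemblies)
    @settings(max_examples=40, deadline=None)
    def test_components_match_union_find(self, asm):
        total = summarize_subgraphs(asm)[-1]
        assert total.n_connected_components == union_find_components(asm)
        for label in asm.subgraph_inventory:
            induced = induce_subgraph(asm, label)
            row = next(s for s in summarize_subgraphs(asm)
                       if s.label == label)
            assert row.n_connected_components == union_find_components(induced)

    @given(assemblies)
    @settings(max_examples=40, deadline=None)
    def test_total_bounds(self, asm):
        rows = summarize_subgraphs(asm)
        total = rows[-1]
        per_label = rows[:-1]
        assert sum(s.n_relationships for s in per_label) >= sum(
            1 for r in asm.relations if r.subgraphs)
        assert total.n_citations <= max(
            sum(s.n_citations for s in per_label), total.n_citations)
        for s in rows:
            assert s.n_connected_components <= s.n_entities
            assert s.n_citations <= s.n_relationships or s.n_relationships == 0

    def test_relabeling_preserves_summary_shape(self, gaba_script):
        asm = parse_bel_subset(gaba_script)
        mapping = {e: BioEntity(e.function, e.namespace, e.name + "X")
                   for e in asm.entities}
        rows_a = summarize_subgraphs(asm)
        rows_b = summarize_subgraphs(relabel_entities(asm, mapping))
        assert rows_a == rows_b


class TestReferenceTable:
    def test_truncation_reproduces_printed_rates_except_stroke(self):
        """All reference rows except the flagged discrepant one satisfy
        printed_rate == trunc2(100 * n_comorbidity_genes / 2901)."""
        from comorbnet import pleiotropy_rate

        df = comorbidity_reference()
        assert len(df) == 22
        mismatches = []
        for row in df.itertuples():
            rate = pleiotropy_rate(row.n_comorbidity_genes,
                                   EPILEPSY_N_GENES).rate_percent
            if rate != pytest.approx(row.printed_rate_percent):
                mismatches.append(row.condition)
        assert set(mismatches) == DISCREPANT_CONDITIONS
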