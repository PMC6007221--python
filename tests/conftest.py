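"""Shared fixtures: small hand-built corpora and assemblies."""

from __future__ import annotations

import pytest

from comorbnet import (
    BioEntity,
    CausalRelation,
    CorpusIndex,
    KnowledgeAssembly,
)

CITE = ("PubMed", "1000")


def protein(name: str) -> BioEntity:
    return BioEntity("protein", "HGNC", name)


def process(name: str) -> BioEntity:
    return BioEntity("bioprocess", "GO", name)


def make_assembly(edges, relation="increases", label=None,
                  citation=CITE) -> KnowledgeAssembly:
    """Assembly from (subject, object) entity pairs, all with one relation
    type, citation and optional subgraph label."""
    labels = frozenset() if label is None else frozenset({label})
    relations = tuple(
        CausalRelation(u, relation, v, citation, subgraphs=labels)
        for u, v in edges
    )
    return KnowledgeAssembly(frozenset(), relations)


@pytest.fixture
def toy_corpus() -> CorpusIndex:
    """Six documents, two diseases, four genes with known frequencies."""
    return CorpusIndex(
        documents=frozenset({"d1", "d2", "d3", "d4", "d5", "d6"}),
        doc_diseases={
            "d1": frozenset({"epilepsy"}),
            "d2": frozenset({"epilepsy", "diabetes"}),
            "d3": frozenset({"diabetes"}),
            "d4": frozenset({"epilepsy"}),
        },
        doc_genes={
            "d1": frozenset({"SCN1A", "GABRA1"}),
            "d2": frozenset({"SCN1A", "INS"}),
            "d3": frozenset({"INS"}),
            "d4": frozenset({"SCN1A"}),
            "d5": frozenset({"ACTB"}),
            "d6": frozenset({"ACTB"}),
        },
    )


@pytest.fixture
def gaba_script() -> str:
    return '''# toy epilepsy fragment
SET Citation = {"PubMed", "101"}
SET Evidence = "carbamazepine blocks sodium channels"
SET Subgraph = "Gaba subgraph"
p(HGNC:SCN1A) decreases bp(GO:"neuronal action potential")
p(HGNC:GABRA1) increases bp(GO:"inhibitory synaptic transmission")
SET Citation = {"PubMed", "102"}
SET Subgraph = {"Gaba subgraph", "Adenosine signaling subgraph"}
a(CHEBI:adenosine) increases p(HGNC:ADORA1)
UNSET Subgraph
p(HGNC:ADK) decreases a(CHEBI:adenosine)
'''


@pytest.fixture
def chain_assembly() -> KnowledgeAssembly:
    """s -> a -> b -> t"""
    s, a, b = protein("S"), protein("A"), protein("B")
    t = process("seizure")
    return make_assembly([(s, a), (a, b), (b, t)])


@pytest.fixture
def diamond_assembly() -> KnowledgeAssembly:
    """s -> a -> t and s -> b -> t (two tied shortest paths)."""
    s, a, b = protein("S"), protein("A"), protein("B")
    t = process("seizure")
    return make_assembly([(s, a), (a, t), (s, b), (b, t)])
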