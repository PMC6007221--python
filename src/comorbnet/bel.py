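"""A minimal Biological Expression Language (BEL) knowledge-assembly model.

The dialect supported here covers what entity-level causal analysis needs and
nothing more: simple terms ``a()``, ``p()``, ``g()``, ``r()``, ``bp()``,
``path()`` and ``complex()`` with a single ``NAMESPACE:Name`` argument, eight
relation types (five causal, three associative), and the annotation keywords
``SET``/``UNSET`` for ``Citation``, ``Evidence`` and ``Subgraph``.  Nested
terms, protein modifications and variants are rejected with a parse error
rather than silently degraded.

Every statement becomes one :class:`CausalRelation` carrying the citation and
subgraph annotations active at its line.  Relations are a multiset: the same
subject/relation/object triple curated from two citations counts twice.

Subgraph labels partition the assembly into candidate mechanisms; a label is
free annotation, so a relation may belong to several mechanisms or to none.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, NamedTuple, Optional

import networkx as nx

from .errors import (
    BELParseError,
    InvalidInputError,
    MissingCitationError,
    SchemaValidationError,
    UnknownLabelError,
)

__all__ = [
    "BioEntity",
    "CausalRelation",
    "KnowledgeAssembly",
    "SubgraphSummary",
    "ParseReport",
    "FUNCTIONS",
    "CAUSAL_RELATIONS",
    "RELATIONS",
    "parse_bel_subset",
    "parse_bel_subset_with_report",
    "parse_term",
    "serialize_bel",
    "read_bel",
    "write_bel",
    "read_nodelink",
    "write_nodelink",
    "induce_subgraph",
    "summarize_subgraphs",
    "to_networkx",
]

FUNCTIONS = frozenset(
    {"abundance", "protein", "gene", "rna", "bioprocess", "pathology",
     "complex"}
)

CAUSAL_RELATIONS = frozenset(
    {"increases", "directly_increases", "decreases", "directly_decreases",
     "regulates"}
)
RELATIONS = CAUSAL_RELATIONS | frozenset(
    {"association", "positive_correlation", "negative_correlation"}
)

_FUNC_TO_ABBREV = {
    "abundance": "a",
    "protein": "p",
    "gene": "g",
    "rna": "r",
    "bioprocess": "bp",
    "pathology": "path",
    "complex": "complex",
}
_ABBREV_TO_FUNC = {v: k for k, v in _FUNC_TO_ABBREV.items()}

# BEL-conventional spellings and arrow shorthands accepted on input
_RELATION_ALIASES = {
    "increases": "increases",
    "->": "increases",
    "directlyIncreases": "directly_increases",
    "=>": "directly_increases",
    "decreases": "decreases",
    "-|": "decreases",
    "directlyDecreases": "directly_decreases",
    "=|": "directly_decreases",
    "regulates": "regulates",
    "reg": "regulates",
    "association": "association",
    "--": "association",
    "positiveCorrelation": "positive_correlation",
    "pos": "positive_correlation",
    "negativeCorrelation": "negative_correlation",
    "neg": "negative_correlation",
}
_RELATION_TO_BEL = {
    "increases": "increases",
    "directly_increases": "directlyIncreases",
    "decreases": "decreases",
    "directly_decreases": "directlyDecreases",
    "regulates": "regulates",
    "association": "association",
    "positive_correlation": "positiveCorrelation",
    "negative_correlation": "negativeCorrelation",
}
for _snake in RELATIONS:
    _RELATION_ALIASES.setdefault(_snake, _snake)


@dataclass(frozen=True, order=True)
class BioEntity:
    """A typed biological entity, identified by (function, namespace, name)."""

    function: str
    namespace: str
    name: str

    def __post_init__(self):
        if self.function not in FUNCTIONS:
            raise InvalidInputError(f"unknown function {self.function!r}")
        if not self.namespace or not self.name:
            raise InvalidInputError("namespace and name must be non-empty")

    def as_bel(self) -> str:
        name = self.name
        if re.search(r"[\s()\"]", name):
            name = '"' + name.replace('"', '\\"') + '"'
        return f"{_FUNC_TO_ABBREV[self.function]}({self.namespace}:{name})"

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.as_bel()


@dataclass(frozen=True)
class CausalRelation:
    """One curated statement: subject --relation--> object, with provenance.

    ``citation`` is a ``(type, identifier)`` pair such as
    ``("PubMed", "12345")``; ``subgraphs`` are the mechanism labels active
    when the statement was curated (possibly empty).
    """

    subject: BioEntity
    relation: str
    object: BioEntity
    citation: tuple[str, str]
    evidence: Optional[str] = None
    subgraphs: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.relation not in RELATIONS:
            raise InvalidInputError(f"unknown relation {self.relation!r}")
        citation = (str(self.citation[0]), str(self.citation[1]))
        if not citation[1]:
            raise InvalidInputError("citation identifier must be non-empty")
        object.__setattr__(self, "citation", citation)
        object.__setattr__(self, "subgraphs", frozenset(self.subgraphs))

    @property
    def is_causal(self) -> bool:
        return self.relation in CAUSAL_RELATIONS

    def as_bel(self) -> str:
        return (f"{self.subject.as_bel()} {_RELATION_TO_BEL[self.relation]} "
                f"{self.object.as_bel()}")


@dataclass(frozen=True)
class KnowledgeAssembly:
    """A curated causal graph: entities, a multiset of relations, and the
    inventory of subgraph (mechanism) labels.

    The inventory may contain labels with no relations (declared but empty
    mechanisms); it always contains every label used by a relation.
    """

    entities: frozenset[BioEntity]
    relations: tuple[CausalRelation, ...]
    subgraph_inventory: frozenset[str] = frozenset()

    def __post_init__(self):
        entities = frozenset(self.entities)
        relations = tuple(self.relations)
        used_labels: set[str] = set()
        for rel in relations:
            used_labels |= rel.subgraphs
        inventory = frozenset(self.subgraph_inventory) | used_labels
        endpoints = {e for r in relations for e in (r.subject, r.object)}
        object.__setattr__(self, "entities", entities | endpoints)
        object.__setattr__(self, "relations", relations)
        object.__setattr__(self, "subgraph_inventory", inventory)

    # -- structural equality up to relation order --------------------------

    def isomorphic_to(self, other: "KnowledgeAssembly") -> bool:
        """Structural equality: same entities, same relation multiset
        (order-insensitive), same label inventory."""
        return (
            self.entities == other.entities
            and Counter(self.relations) == Counter(other.relations)
            and self.subgraph_inventory == other.subgraph_inventory
        )

    def citations(self) -> frozenset[tuple[str, str]]:
        return frozenset(r.citation for r in self.relations)

    def __len__(self) -> int:
        return len(self.relations)


class SubgraphSummary(NamedTuple):
    """Descriptive statistics of one labelled mechanism subgraph."""

    label: str
    n_entities: int
    n_relationships: int
    n_connected_components: int
    n_citations: int


@dataclass
class ParseReport:
    """Book-keeping from a (possibly lenient) parse run."""

    n_statements: int = 0
    n_skipped: int = 0
    skipped_lines: list[tuple[int, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# BEL script parsing
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(
    r"(?P<func>[A-Za-z]+)\(\s*(?P<ns>[A-Za-z0-9_.-]+)\s*:\s*"
    r"(?P<name>\"(?:[^\"\\]|\\.)*\"|[^\s()\"]+)\s*\)"
)
_TERM_SRC = (
    r"[A-Za-z]+\(\s*[A-Za-z0-9_.-]+\s*:\s*"
    r"(?:\"(?:[^\"\\]|\\.)*\"|[^\s()\"]+)\s*\)"
)
_STATEMENT_RE = re.compile(
    rf"^(?P<subject>{_TERM_SRC})\s+(?P<rel>\S+)\s+(?P<object>{_TERM_SRC})$"
)
_SET_RE = re.compile(r"^SET\s+(?P<key>\w+)\s*=\s*(?P<value>.+)$", re.I)
_UNSET_RE = re.compile(r"^UNSET\s+(?P<key>\w+|ALL)$", re.I)


def _unquote(token: str) -> str:
    token = token.strip()
    if token.startswith('"') and token.endswith('"') and len(token) >= 2:
        return token[1:-1].replace('\\"', '"')
    return token


def _parse_list(value: str, lineno: int) -> list[str]:
    value = value.strip()
    if value.startswith("{"):
        if not value.endswith("}"):
            raise BELParseError("unterminated annotation list", lineno)
        inner = value[1:-1]
        parts = re.findall(r'"(?:[^"\\]|\\.)*"|[^,\s]+', inner)
        return [_unquote(p) for p in parts if p.strip(", ")]
    return [_unquote(value)]


def _parse_term(match: re.Match, lineno: int) -> BioEntity:
    abbrev = match.group("func")
    func = _ABBREV_TO_FUNC.get(abbrev)
    if func is None:
        raise BELParseError(f"unsupported term function {abbrev!r}", lineno)
    try:
        return BioEntity(func, match.group("ns"), _unquote(match.group("name")))
    except InvalidInputError as exc:
        raise BELParseError(str(exc), lineno) from exc


def parse_term(text: str) -> BioEntity:
    """Parse a single BEL term such as ``p(HGNC:GABRA1)`` or
    ``bp(GO:"neuronal action potential")``."""
    m = _TERM_RE.fullmatch(text.strip())
    if m is None:
        raise BELParseError(f"cannot parse term: {text!r}", 1)
    return _parse_term(m, 1)


def parse_bel_subset_with_report(
    text: str, lenient: bool = False
) -> tuple[KnowledgeAssembly, ParseReport]:
    """Parse a BEL script in the supported dialect.

    In strict mode (default) any unsupported or malformed line raises
    :class:`BELParseError` with its line number.  With ``lenient=True`` such
    lines are skipped and counted in the returned :class:`ParseReport`
    instead, so externally curated files with richer syntax can still be
    ingested partially.
    """
    citation: Optional[tuple[str, str]] = None
    evidence: Optional[str] = None
    subgraphs: frozenset[str] = frozenset()
    relations: list[CausalRelation] = []
    inventory: set[str] = set()
    report = ParseReport()

    def fail(exc: BELParseError, raw: str):
        if lenient:
            report.n_skipped += 1
            report.skipped_lines.append((exc.line_number, raw))
        else:
            raise exc

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = _SET_RE.match(line)
        if m:
            key = m.group("key").lower()
            values = _parse_list(m.group("value"), lineno)
            if key == "citation":
                if len(values) == 2:
                    citation = (values[0], values[1])
                elif len(values) == 3:  # (type, name, identifier) form
                    citation = (values[0], values[2])
                else:
                    fail(BELParseError(
                        "Citation needs 2 or 3 fields", lineno), raw)
                    continue
                if not citation[1]:
                    fail(BELParseError(
                        "citation identifier must be non-empty", lineno), raw)
                    citation = None
            elif key == "evidence" or key == "support":
                evidence = values[0]
            elif key == "subgraph":
                subgraphs = frozenset(v for v in values if v)
                inventory |= subgraphs
            else:
                fail(BELParseError(
                    f"unsupported annotation {m.group('key')!r}", lineno), raw)
            continue
        m = _UNSET_RE.match(line)
        if m:
            key = m.group("key").lower()
            if key == "all":
                citation, evidence, subgraphs = None, None, frozenset()
            elif key == "citation":
                citation = None
            elif key in ("evidence", "support"):
                evidence = None
            elif key == "subgraph":
                subgraphs = frozenset()
            else:
                fail(BELParseError(
                    f"unsupported annotation {m.group('key')!r}", lineno), raw)
            continue
        m = _STATEMENT_RE.match(line)
        if not m:
            fail(BELParseError(f"cannot parse line: {line!r}", lineno), raw)
            continue
        relation = _RELATION_ALIASES.get(m.group("rel"))
        if relation is None:
            fail(BELParseError(
                f"unknown relation keyword {m.group('rel')!r}", lineno), raw)
            continue
        if citation is None:
            fail(MissingCitationError(
                "statement before any SET Citation", lineno), raw)
            continue
        subj_m = _TERM_RE.match(m.group("subject"))
        obj_m = _TERM_RE.match(m.group("object"))
        try:
            subject = _parse_term(subj_m, lineno)
            obj = _parse_term(obj_m, lineno)
        except BELParseError as exc:
            fail(exc, raw)
            continue
        relations.append(
            CausalRelation(subject, relation, obj, citation, evidence,
                           subgraphs)
        )
        report.n_statements += 1

    assembly = KnowledgeAssembly(frozenset(), tuple(relations),
                                 frozenset(inventory))
    return assembly, report


def parse_bel_subset(text: str, lenient: bool = False) -> KnowledgeAssembly:
    """Parse BEL script text; see :func:`parse_bel_subset_with_report`."""
    assembly, _ = parse_bel_subset_with_report(text, lenient=lenient)
    return assembly


def serialize_bel(assembly: KnowledgeAssembly) -> str:
    """Render an assembly back to BEL script.

    Relations are grouped under their ``SET`` annotations in original order;
    inventory labels that annotate no relation are declared by an empty
    ``SET Subgraph`` / ``UNSET Subgraph`` block so that a re-parse recovers
    the full inventory.
    """
    lines: list[str] = []
    current_citation: Optional[tuple[str, str]] = None
    current_evidence: Optional[str] = None
    current_subgraphs: Optional[frozenset[str]] = None

    def quote(s: str) -> str:
        return '"' + s.replace('"', '\\"') + '"'

    for rel in assembly.relations:
        if rel.citation != current_citation:
            lines.append(
                f"SET Citation = {{{quote(rel.citation[0])}, "
                f"{quote(rel.citation[1])}}}"
            )
            current_citation = rel.citation
        if rel.evidence != current_evidence:
            if rel.evidence is None:
                lines.append("UNSET Evidence")
            else:
                lines.append(f"SET Evidence = {quote(rel.evidence)}")
            current_evidence = rel.evidence
        if rel.subgraphs != current_subgraphs:
            if not rel.subgraphs:
                lines.append("UNSET Subgraph")
            else:
                inner = ", ".join(quote(s) for s in sorted(rel.subgraphs))
                lines.append(f"SET Subgraph = {{{inner}}}")
            current_subgraphs = rel.subgraphs
        lines.append(rel.as_bel())

    used = {s for r in assembly.relations for s in r.subgraphs}
    for label in sorted(assembly.subgraph_inventory - used):
        lines.append(f'SET Subgraph = {quote(label)}')
        lines.append("UNSET Subgraph")

    # isolated entities: declare them via a self-association? No — keep them
    # as comments is lossy; the dialect has no isolated-node statement, so
    # isolated entities only round-trip through node-link JSON.
    return "\n".join(lines) + ("\n" if lines else "")


def read_bel(path: str | Path, lenient: bool = False) -> KnowledgeAssembly:
    return parse_bel_subset(Path(path).read_text(encoding="utf-8"),
                            lenient=lenient)


def write_bel(assembly: KnowledgeAssembly, path: str | Path) -> None:
    Path(path).write_text(serialize_bel(assembly), encoding="utf-8")


# ---------------------------------------------------------------------------
# node-link JSON
# ---------------------------------------------------------------------------

def _entity_to_dict(e: BioEntity) -> dict:
    return {"function": e.function, "namespace": e.namespace, "name": e.name}


def _entity_from_dict(d: dict, where: str) -> BioEntity:
    for key in ("function", "namespace", "name"):
        if key not in d:
            raise SchemaValidationError(f"{where}.{key}", "missing")
    try:
        return BioEntity(d["function"], d["namespace"], d["name"])
    except InvalidInputError as exc:
        raise SchemaValidationError(where, str(exc)) from exc


def write_nodelink(assembly: KnowledgeAssembly, path: str | Path) -> None:
    """Write the assembly as node-link JSON with stable ordering: entities
    sorted by (function, namespace, name), relations in curation order."""
    payload = {
        "entities": [_entity_to_dict(e) for e in sorted(assembly.entities)],
        "relations": [
            {
                "subject": _entity_to_dict(r.subject),
                "relation": r.relation,
                "object": _entity_to_dict(r.object),
                "citation": list(r.citation),
                "evidence": r.evidence,
                "subgraphs": sorted(r.subgraphs),
            }
            for r in assembly.relations
        ],
        "subgraph_inventory": sorted(assembly.subgraph_inventory),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_nodelink(path: str | Path) -> KnowledgeAssembly:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    for key in ("entities", "relations", "subgraph_inventory"):
        if key not in payload:
            raise SchemaValidationError(key, "missing top-level key")
    entities = frozenset(
        _entity_from_dict(d, f"entities[{i}]")
        for i, d in enumerate(payload["entities"])
    )
    relations = []
    for i, d in enumerate(payload["relations"]):
        where = f"relations[{i}]"
        for key in ("subject", "relation", "object", "citation"):
            if key not in d:
                raise SchemaValidationError(f"{where}.{key}", "missing")
        if d["relation"] not in RELATIONS:
            raise SchemaValidationError(
                f"{where}.relation", f"unknown relation {d['relation']!r}")
        citation = d["citation"]
        if (not isinstance(citation, (list, tuple)) or len(citation) != 2
                or not citation[1]):
            raise SchemaValidationError(
                f"{where}.citation", "must be a [type, identifier] pair")
        relations.append(
            CausalRelation(
                _entity_from_dict(d["subject"], f"{where}.subject"),
                d["relation"],
                _entity_from_dict(d["object"], f"{where}.object"),
                (citation[0], citation[1]),
                d.get("evidence"),
                frozenset(d.get("subgraphs", ())),
            )
        )
    return KnowledgeAssembly(entities, tuple(relations),
                             frozenset(payload["subgraph_inventory"]))


# ---------------------------------------------------------------------------
# subgraph operations
# ---------------------------------------------------------------------------

def induce_subgraph(assembly: KnowledgeAssembly, label: str) -> KnowledgeAssembly:
    """The sub-assembly of relations annotated with ``label`` and their
    endpoint entities."""
    if label not in assembly.subgraph_inventory:
        raise UnknownLabelError(label, sorted(assembly.subgraph_inventory))
    relations = tuple(r for r in assembly.relations if label in r.subgraphs)
    return KnowledgeAssembly(frozenset(), relations, frozenset({label}))


def to_networkx(
    assembly: KnowledgeAssembly, causal_only: bool = False
) -> nx.MultiDiGraph:
    """Project the assembly onto a directed multigraph; nodes are
    :class:`BioEntity`, parallel edges keep per-relation metadata."""
    g = nx.MultiDiGraph()
    g.add_nodes_from(assembly.entities)
    for r in assembly.relations:
        if causal_only and not r.is_causal:
            continue
        g.add_edge(r.subject, r.object, relation=r.relation,
                   citation=r.citation, subgraphs=r.subgraphs)
    return g


def _summary_of(assembly: KnowledgeAssembly, label: str) -> SubgraphSummary:
    g = to_networkx(assembly)
    return SubgraphSummary(
        label=label,
        n_entities=len(assembly.entities),
        n_relationships=len(assembly.relations),
        n_connected_components=(
            nx.number_connected_components(g.to_undirected())
            if assembly.entities else 0
        ),
        n_citations=len(assembly.citations()),
    )


def summarize_subgraphs(
    assembly: KnowledgeAssembly, total_label: str = "Total"
) -> list[SubgraphSummary]:
    """Per-label statistics plus a Total row over the full assembly.

    Connected components are computed on the undirected projection.
    Citations are de-duplicated per label and again for the Total, so the
    Total citation count is at most the per-label sum (a citation may
    support several mechanisms).
    """
    out = [
        _summary_of(induce_subgraph(assembly, label), label)
        for label in sorted(assembly.subgraph_inventory)
    ]
    out.append(_summary_of(assembly, total_label))
    return out


def relabel_entities(
    assembly: KnowledgeAssembly, mapping: dict[BioEntity, BioEntity]
) -> KnowledgeAssembly:
    """Rename entities throughout (used for invariance checks)."""
    def m(e: BioEntity) -> BioEntity:
        return mapping.get(e, e)

    return KnowledgeAssembly(
        frozenset(m(e) for e in assembly.entities),
        tuple(replace(r, subject=m(r.subject), object=m(r.object))
              for r in assembly.relations),
        assembly.subgraph_inventory,
    )
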