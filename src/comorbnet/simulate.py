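"""Synthetic corpora and knowledge assemblies with planted ground truth.

Every pipeline stage is testable without external downloads:

* :func:`simulate_corpus` emulates a gene/disease-tagged literature index.
  Documents belong to a background pool, to one disease, or to a disease
  pair (the AND-query stratum).  Each gene is mentioned in each document
  independently with a baseline probability; genes planted for a document's
  disease context are mentioned with ``enrichment_factor * baseline``
  instead.  Mentions are presence/absence, mirroring the document-frequency
  scoring model.

* :func:`simulate_assembly` builds a causal knowledge assembly of labelled
  mechanism blocks.  Seed (drug-target) genes concentrate in designated
  planted blocks; causal source->sink chains of prescribed length are
  embedded so that they are provably the unique shortest paths (random
  edges are never aimed at chain nodes, so no shortcut can arise); an
  optional controller node gets causal edges into two or more planted
  chains.

Both generators are deterministic: the same config (including its seed)
yields byte-identical serialized output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import networkx as nx
import numpy as np

from .bel import BioEntity, CausalRelation, KnowledgeAssembly, to_networkx
from .corpus import CorpusIndex
from .errors import ConfigError

__all__ = [
    "CorpusSimConfig",
    "GraphSimConfig",
    "PlantedPath",
    "SimGroundTruth",
    "simulate_corpus",
    "simulate_assembly",
]

ContextKey = Union[str, tuple[str, str]]


def _norm_pair(pair: tuple[str, str]) -> tuple[str, str]:
    a, b = sorted(pair)
    return (a, b)


@dataclass(frozen=True)
class SimGroundTruth:
    """What was planted, for recovery testing."""

    planted_genes: Mapping[ContextKey, frozenset[str]] = field(
        default_factory=dict)
    planted_subgraphs: tuple[str, ...] = ()
    planted_paths: Mapping[tuple[BioEntity, BioEntity],
                           tuple[BioEntity, ...]] = field(default_factory=dict)
    planted_controller: Optional[BioEntity] = None
    seed_genes: frozenset[str] = frozenset()


@dataclass(frozen=True)
class CorpusSimConfig:
    """Configuration of the synthetic literature index.

    Defaults emulate a two-disease comorbidity study slice: one index
    disease with a comorbid condition, joint documents for the AND query,
    a background pool, and a planted gene set per context that is mentioned
    ``enrichment_factor`` times more often than baseline.
    """

    n_background_docs: int = 600
    disease_docs: Mapping[str, int] = field(
        default_factory=lambda: {"epilepsy": 200, "migraine": 120})
    pair_docs: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: {("epilepsy", "migraine"): 60})
    n_genes: int = 300
    baseline: float = 0.02
    planted: Mapping[ContextKey, frozenset[str]] = field(default_factory=dict)
    enrichment_factor: float = 10.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "disease_docs", dict(self.disease_docs))
        object.__setattr__(
            self, "pair_docs",
            {_norm_pair(k): v for k, v in self.pair_docs.items()})
        planted = {}
        for key, genes in self.planted.items():
            norm = _norm_pair(key) if isinstance(key, tuple) else key
            planted[norm] = frozenset(genes)
        object.__setattr__(self, "planted", planted)
        if not 0 < self.baseline < 1:
            raise ConfigError("baseline must be in (0, 1)")
        if self.enrichment_factor < 1:
            raise ConfigError("enrichment_factor must be >= 1")
        if self.enrichment_factor * self.baseline > 1:
            raise ConfigError("enrichment_factor * baseline must be <= 1")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if any(v < 0 for v in self.disease_docs.values()) or \
                any(v < 0 for v in self.pair_docs.values()) or \
                self.n_background_docs < 0:
            raise ConfigError("document counts must be >= 0")
        total = (self.n_background_docs + sum(self.disease_docs.values())
                 + sum(self.pair_docs.values()))
        if total < 2:
            raise ConfigError(
                "corpus needs >=2 documents so a query background exists")
        vocab = set(self.vocabulary())
        for key, genes in planted.items():
            if not genes <= vocab:
                raise ConfigError(
                    f"planted genes for {key!r} not in the vocabulary")
        for pair in self.pair_docs:
            for d in pair:
                if d not in self.disease_docs:
                    raise ConfigError(
                        f"pair {pair} references unknown disease {d!r}")

    def vocabulary(self) -> tuple[str, ...]:
        width = max(4, len(str(self.n_genes)))
        return tuple(f"G{i:0{width}d}" for i in range(1, self.n_genes + 1))


def simulate_corpus(
    config: CorpusSimConfig,
) -> tuple[CorpusIndex, SimGroundTruth]:
    """Draw a corpus; returns the index and the planted ground truth."""
    rng = np.random.default_rng(config.seed)
    vocab = np.array(config.vocabulary())
    n_genes = len(vocab)
    vocab_pos = {g: i for i, g in enumerate(vocab)}

    documents: set[str] = set()
    doc_diseases: dict[str, frozenset[str]] = {}
    doc_genes: dict[str, frozenset[str]] = {}

    def emit(prefix: str, n_docs: int, diseases: frozenset[str],
             context: Optional[ContextKey]) -> None:
        probs = np.full(n_genes, config.baseline)
        for g in config.planted.get(context, frozenset()):
            probs[vocab_pos[g]] = config.baseline * config.enrichment_factor
        hits = rng.random((n_docs, n_genes)) < probs
        for i in range(n_docs):
            doc = f"{prefix}-{i + 1:05d}"
            documents.add(doc)
            if diseases:
                doc_diseases[doc] = diseases
            genes = frozenset(vocab[hits[i]])
            if genes:
                doc_genes[doc] = genes

    emit("bg", config.n_background_docs, frozenset(), None)
    for disease in sorted(config.disease_docs):
        emit(disease, config.disease_docs[disease], frozenset({disease}),
             disease)
    for pair in sorted(config.pair_docs):
        emit("+".join(pair), config.pair_docs[pair], frozenset(pair), pair)

    index = CorpusIndex(frozenset(documents), doc_diseases, doc_genes)
    truth = SimGroundTruth(planted_genes=dict(config.planted))
    return index, truth


# ---------------------------------------------------------------------------
# knowledge-assembly simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedPath:
    """A causal source->sink chain of ``length`` edges embedded in the
    mechanism block with index ``subgraph``."""

    subgraph: int
    length: int


@dataclass(frozen=True)
class GraphSimConfig:
    """Configuration of the synthetic knowledge assembly.

    ``seed_inclusion_base`` is the probability that any one seed gene
    appears in a non-planted mechanism block; planted blocks use
    ``seed_enrichment`` times that.  With ``ensure_mapped`` every block
    receives at least one seed gene, mirroring enrichment runs restricted
    to mechanisms with at least one mapped gene.
    """

    n_subgraphs: int = 8
    genes_per_subgraph: int = 12
    processes_per_subgraph: int = 3
    p_within: float = 0.25
    p_between: float = 0.02
    p_association: float = 0.10
    planted_subgraphs: tuple[int, ...] = (0, 1)
    n_seed_genes: int = 10
    seed_inclusion_base: float = 0.05
    seed_enrichment: float = 12.0
    ensure_mapped: bool = True
    planted_paths: tuple[PlantedPath, ...] = ()
    planted_controller: bool = False
    citation_pool_size: int = 20
    citations_per_subgraph: int = 5
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "planted_subgraphs",
                           tuple(self.planted_subgraphs))
        object.__setattr__(self, "planted_paths", tuple(self.planted_paths))
        if self.n_subgraphs < 1 or self.genes_per_subgraph < 1:
            raise ConfigError("need >=1 subgraph with >=1 gene")
        if not 0 < self.p_between <= self.p_within <= 1:
            raise ConfigError("require 0 < p_between <= p_within <= 1")
        if not 0 <= self.p_association < 1:
            raise ConfigError("p_association must be in [0, 1)")
        if any(not 0 <= k < self.n_subgraphs
               for k in self.planted_subgraphs):
            raise ConfigError("planted subgraph index out of range")
        if not 0 < self.seed_inclusion_base < 1:
            raise ConfigError("seed_inclusion_base must be in (0, 1)")
        if self.seed_enrichment < 1:
            raise ConfigError("seed_enrichment must be >= 1")
        for spec in self.planted_paths:
            if spec.length < 1:
                raise ConfigError("planted path length must be >= 1")
            if spec.length > self.genes_per_subgraph:
                raise ConfigError(
                    "planted path length exceeds the mechanism block size")
            if not 0 <= spec.subgraph < self.n_subgraphs:
                raise ConfigError("planted path subgraph index out of range")
        if self.planted_controller and len(self.planted_paths) < 2:
            raise ConfigError(
                "a shared controller needs >=2 planted paths")

    def labels(self) -> tuple[str, ...]:
        return tuple(f"Mechanism {k + 1:02d} subgraph"
                     for k in range(self.n_subgraphs))


def _seed_symbols(n: int) -> tuple[str, ...]:
    return tuple(f"SEED{i:02d}" for i in range(1, n + 1))


def simulate_assembly(
    config: GraphSimConfig,
) -> tuple[KnowledgeAssembly, SimGroundTruth]:
    """Draw a labelled causal assembly; returns it with its ground truth.

    Construction guarantees that each planted chain is the *unique*
    shortest causal path between its endpoints: no random edge ever points
    at a chain node, so every route into the sink runs through the chain.
    Minimality is re-verified on the finished graph before returning.
    """
    rng = np.random.default_rng(config.seed)
    labels = config.labels()
    seed_syms = _seed_symbols(config.n_seed_genes)
    causal_kinds = np.array(
        ["increases", "decreases", "directly_increases", "regulates"])
    causal_probs = np.array([0.5, 0.3, 0.1, 0.1])
    assoc_kinds = np.array(
        ["association", "positive_correlation", "negative_correlation"])

    pool = [("PubMed", str(7_000_000 + i))
            for i in range(config.citation_pool_size)]
    sub_citations = [
        [pool[j] for j in rng.choice(len(pool),
                                     size=min(config.citations_per_subgraph,
                                              len(pool)),
                                     replace=False)]
        for _ in range(config.n_subgraphs)
    ]

    # -- entities per block ------------------------------------------------
    block_nodes: list[list[BioEntity]] = []
    for k in range(config.n_subgraphs):
        nodes = [BioEntity("protein", "HGNC", f"S{k + 1}G{j + 1:02d}")
                 for j in range(config.genes_per_subgraph)]
        nodes += [BioEntity("bioprocess", "GO", f"process {k + 1}.{j + 1}")
                  for j in range(config.processes_per_subgraph)]
        block_nodes.append(nodes)

    # -- seed-gene placement ----------------------------------------------
    p_planted = min(1.0, config.seed_inclusion_base * config.seed_enrichment)
    seed_members: list[list[str]] = []
    for k in range(config.n_subgraphs):
        p = p_planted if k in config.planted_subgraphs \
            else config.seed_inclusion_base
        chosen = [s for s in seed_syms if rng.random() < p]
        if config.ensure_mapped and not chosen:
            chosen = [seed_syms[int(rng.integers(len(seed_syms)))]]
        seed_members.append(chosen)
        block_nodes[k].extend(
            BioEntity("protein", "HGNC", s) for s in chosen)

    # -- planted chains ----------------------------------------------------
    forbidden_targets: set[BioEntity] = set()
    relations: list[CausalRelation] = []
    planted_paths: dict[tuple[BioEntity, BioEntity], tuple[BioEntity, ...]] = {}
    for i, spec in enumerate(config.planted_paths, start=1):
        src = BioEntity("protein", "HGNC", f"TGT{i:02d}")
        sink = BioEntity("pathology", "MESH", f"planted outcome {i}")
        interior = [BioEntity("protein", "HGNC", f"PP{i:02d}N{j:02d}")
                    for j in range(1, spec.length)]
        chain = [src, *interior, sink]
        label = labels[spec.subgraph]
        cite = sub_citations[spec.subgraph][0]
        for u, v in zip(chain, chain[1:]):
            relations.append(CausalRelation(
                u, "increases", v, cite,
                evidence=f"planted chain {i}", subgraphs=frozenset({label})))
        forbidden_targets.update(chain)
        planted_paths[(src, sink)] = tuple(chain)
        block_nodes[spec.subgraph].extend(chain)

    controller: Optional[BioEntity] = None
    if config.planted_controller:
        controller = BioEntity("protein", "HGNC", "CTRL01")
        for (src, sink), chain in list(planted_paths.items())[:2]:
            target = chain[1] if len(chain) > 2 else chain[-1]
            spec_idx = [p for p in planted_paths].index((src, sink))
            label = labels[config.planted_paths[spec_idx].subgraph]
            relations.append(CausalRelation(
                controller, "increases", target,
                sub_citations[config.planted_paths[spec_idx].subgraph][-1],
                evidence="planted controller", subgraphs=frozenset({label})))
        forbidden_targets.add(controller)

    # -- random edges ------------------------------------------------------
    def draw_edges(nodes_a: list[BioEntity], nodes_b: list[BioEntity],
                   p: float, label_idx: int, labelled: bool) -> None:
        # cross-block edges are left without a mechanism label: a relation
        # bridging two mechanisms belongs to neither annotation
        candidates = [
            (u, v) for u in nodes_a for v in nodes_b
            if u != v and v not in forbidden_targets
            and u != controller and u not in forbidden_targets
        ]
        if not candidates:
            return
        mask = rng.random(len(candidates)) < p
        for (u, v), hit in zip(candidates, mask):
            if not hit:
                continue
            if rng.random() < config.p_association:
                kind = str(assoc_kinds[int(rng.integers(len(assoc_kinds)))])
            else:
                kind = str(rng.choice(causal_kinds, p=causal_probs))
            cites = sub_citations[label_idx]
            cite = cites[int(rng.integers(len(cites)))]
            relations.append(CausalRelation(
                u, kind, v, cite,
                subgraphs=frozenset({labels[label_idx]}) if labelled
                else frozenset()))

    for k in range(config.n_subgraphs):
        draw_edges(block_nodes[k], block_nodes[k], config.p_within, k,
                   labelled=True)
    for k in range(config.n_subgraphs):
        for m in range(config.n_subgraphs):
            if k != m:
                draw_edges(block_nodes[k], block_nodes[m],
                           config.p_between, k, labelled=False)

    entities = frozenset(n for block in block_nodes for n in block)
    if controller is not None:
        entities = entities | {controller}
    assembly = KnowledgeAssembly(entities, tuple(relations),
                                 frozenset(labels))

    # construction should make every planted chain the unique shortest
    # route; verify on the finished graph
    if planted_paths:
        g = to_networkx(assembly, causal_only=True)
        for (src, sink), chain in planted_paths.items():
            found = nx.shortest_path_length(g, src, sink)
            if found != len(chain) - 1:
                raise ConfigError(
                    f"planted path {src.name}->{sink.name} is not shortest "
                    f"(found length {found})")

    truth = SimGroundTruth(
        planted_subgraphs=tuple(labels[k]
                                for k in sorted(set(config.planted_subgraphs))),
        planted_paths=planted_paths,
        planted_controller=controller,
        seed_genes=frozenset(seed_syms),
    )
    return assembly, truth
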