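"""Seed-gene mechanism enrichment over annotated knowledge assemblies.

A *seed set* — typically the known targets of a drug — is mapped onto each
labelled mechanism subgraph by gene-symbol match against the subgraph's
gene-like entities (gene/RNA/protein functions under a gene-symbol
namespace).  Each mechanism gets:

* ``coverage``    — mapped seeds / seeds present anywhere in the assembly,
* ``specificity`` — mapped seeds / gene-like entities in the subgraph,
* ``score``       — the geometric mean ``sqrt(coverage * specificity)``,
  a relative ranking score in [0, 1],
* ``hypergeom_p`` — the upper-tail hypergeometric probability of observing
  at least that many seed hits when drawing the subgraph's gene-like
  entities from the assembly's gene universe, reported alongside as a
  calibrated alternative.

Because the score is only relative, mechanisms are selected by empirical
percentile among the candidates with at least one mapped gene (ties at the
threshold included).  Comparative enrichment runs the same seed set against
two disease-context assemblies and intersects the selections by normalized
mechanism label.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .bel import KnowledgeAssembly, induce_subgraph
from .errors import InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "SeedSet",
    "SubgraphScore",
    "ComparativeResult",
    "GENE_FUNCTIONS",
    "DEFAULT_GENE_NAMESPACES",
    "gene_symbols",
    "map_seed_genes",
    "score_subgraph",
    "score_all_subgraphs",
    "select_top_percentile",
    "comparative_enrichment",
    "normalize_label",
]

#: entity functions that can carry a gene symbol
GENE_FUNCTIONS = frozenset({"gene", "rna", "protein"})
#: namespaces recognized as holding gene symbols
DEFAULT_GENE_NAMESPACES = ("HGNC", "SYMBOL")


@dataclass(frozen=True)
class SeedSet:
    """A set of query gene symbols (e.g. one drug's known targets)."""

    genes: frozenset[str]
    provenance: str = ""

    def __post_init__(self):
        genes = frozenset(g.strip().upper() for g in self.genes if g.strip())
        if not genes:
            raise InvalidInputError("seed set must contain >=1 gene symbol")
        object.__setattr__(self, "genes", genes)

    @classmethod
    def from_file(cls, path: str | Path, provenance: str = "") -> "SeedSet":
        """Read one gene symbol per line; blank lines and ``#`` comments are
        ignored."""
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        genes = frozenset(
            ln.strip().upper() for ln in lines
            if ln.strip() and not ln.lstrip().startswith("#")
        )
        return cls(genes, provenance or str(path))


@dataclass(frozen=True)
class SubgraphScore:
    """Enrichment result of one mechanism subgraph for a seed set."""

    label: str
    mapped_genes: frozenset[str]
    coverage: float
    specificity: float
    score: float
    hypergeom_p: float


@dataclass(frozen=True)
class ComparativeResult:
    """Two-context enrichment: per-context selections and their overlap.

    ``shared`` holds normalized labels selected in both contexts;
    ``score_pairs`` maps each shared normalized label to the (context A,
    context B) scores.
    """

    contexts: tuple[str, str]
    selected: dict[str, tuple[str, ...]]
    shared: frozenset[str]
    score_pairs: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        for name in self.contexts:
            norm = {normalize_label(lb) for lb in self.selected.get(name, ())}
            if not self.shared <= norm:
                raise InvalidInputError(
                    f"shared labels must be a subset of the {name} selection")


def gene_symbols(
    assembly: KnowledgeAssembly,
    namespaces: Sequence[str] = DEFAULT_GENE_NAMESPACES,
) -> frozenset[str]:
    """Uppercased gene symbols among the assembly's gene-like entities."""
    ns = {n.upper() for n in namespaces}
    return frozenset(
        e.name.upper()
        for e in assembly.entities
        if e.function in GENE_FUNCTIONS and e.namespace.upper() in ns
    )


def map_seed_genes(
    assembly: KnowledgeAssembly,
    seeds: SeedSet,
    namespaces: Sequence[str] = DEFAULT_GENE_NAMESPACES,
) -> dict[str, frozenset[str]]:
    """For every mechanism label, the seed genes found among its gene-like
    entities (case-insensitive symbol match).  Labels with no hit map to the
    empty set."""
    return {
        label: frozenset(
            seeds.genes & gene_symbols(induce_subgraph(assembly, label),
                                       namespaces)
        )
        for label in sorted(assembly.subgraph_inventory)
    }


def score_subgraph(
    assembly: KnowledgeAssembly,
    label: str,
    seeds: SeedSet,
    namespaces: Sequence[str] = DEFAULT_GENE_NAMESPACES,
) -> SubgraphScore:
    """Score one mechanism subgraph for a seed set.

    The hypergeometric tail treats the assembly's gene universe (size M,
    of which K are seeds) as the urn and the subgraph's gene-like entities
    (n) as the draw; it reports P(X >= observed hits).
    """
    universe = gene_symbols(assembly, namespaces)
    subgraph_genes = gene_symbols(induce_subgraph(assembly, label), namespaces)
    seeds_in_assembly = seeds.genes & universe
    mapped = seeds.genes & subgraph_genes

    coverage = (len(mapped) / len(seeds_in_assembly)
                if seeds_in_assembly else 0.0)
    specificity = len(mapped) / len(subgraph_genes) if subgraph_genes else 0.0
    score = math.sqrt(coverage * specificity)
    p = float(stats.hypergeom.sf(
        len(mapped) - 1, len(universe), len(seeds_in_assembly),
        len(subgraph_genes)))
    return SubgraphScore(label, mapped, coverage, specificity, score,
                         min(p, 1.0))


def score_all_subgraphs(
    assembly: KnowledgeAssembly,
    seeds: SeedSet,
    namespaces: Sequence[str] = DEFAULT_GENE_NAMESPACES,
) -> list[SubgraphScore]:
    """Score every mechanism label in the inventory (sorted by label)."""
    return [
        score_subgraph(assembly, label, seeds, namespaces)
        for label in sorted(assembly.subgraph_inventory)
    ]


def select_top_percentile(
    scores: Sequence[SubgraphScore],
    fraction: float = 0.10,
) -> list[str]:
    """Labels of mechanisms in the top ``fraction`` of candidate scores.

    Candidates are the scores with at least one mapped gene.  The threshold
    is the empirical (1 - fraction)-quantile of candidate scores (linear
    interpolation); every candidate scoring at or above it is selected, so
    ties at the threshold are all kept and the selection is never empty when
    candidates exist.
    """
    if not 0 < fraction < 1:
        raise InvalidInputError("fraction must be in (0, 1)")
    candidates = [s for s in scores if s.mapped_genes]
    if not candidates:
        logger.warning("select_top_percentile: no subgraph has a mapped gene")
        return []
    values = np.array([s.score for s in candidates])
    threshold = float(np.quantile(values, 1.0 - fraction))
    return [s.label for s in candidates if s.score >= threshold]


_SUFFIX_RE = re.compile(r"\s*(sub-?graph)\s*$")


def normalize_label(label: str) -> str:
    """Lowercase and strip a trailing 'subgraph'/'sub-graph' suffix, so that
    e.g. 'Gaba subgraph' and 'GABA sub-graph' compare equal across
    assemblies."""
    return _SUFFIX_RE.sub("", label.strip().lower()).strip()


def comparative_enrichment(
    assembly_a: KnowledgeAssembly,
    assembly_b: KnowledgeAssembly,
    seeds: SeedSet,
    fraction: float = 0.10,
    contexts: tuple[str, str] = ("A", "B"),
    namespaces: Sequence[str] = DEFAULT_GENE_NAMESPACES,
) -> ComparativeResult:
    """Run enrichment + selection independently in two disease contexts and
    intersect the selected mechanisms by normalized label."""
    if not assembly_a.relations or not assembly_b.relations:
        raise InvalidInputError("both context assemblies must be non-empty")
    results: dict[str, tuple[str, ...]] = {}
    by_norm: dict[str, dict[str, Optional[SubgraphScore]]] = {}
    for name, assembly in zip(contexts, (assembly_a, assembly_b)):
        scores = score_all_subgraphs(assembly, seeds, namespaces)
        selected = tuple(select_top_percentile(scores, fraction))
        results[name] = selected
        lookup = {normalize_label(s.label): s for s in scores}
        for label in selected:
            by_norm.setdefault(normalize_label(label), {})[name] = \
                lookup[normalize_label(label)]
    shared = frozenset(
        norm for norm, per in by_norm.items() if len(per) == 2
    )
    score_pairs = {
        norm: (by_norm[norm][contexts[0]].score,
               by_norm[norm][contexts[1]].score)
        for norm in sorted(shared)
    }
    return ComparativeResult(contexts, results, shared, score_pairs)
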