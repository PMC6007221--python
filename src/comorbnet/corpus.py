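"""Literature co-occurrence layer: disease queries, relative-entropy gene
association, pleiotropy rates and prevalence ratios.

The model emulates a gene/disease-tagged document index (such as the SCAIView
index over MEDLINE): every document carries a set of disease terms and a set
of gene symbols, at presence/absence granularity.  A gene is called
*associated* with a disease query when it is mentioned in at least one query
document and occurs more frequently inside the query result than in the rest
of the corpus — the positive relative-entropy criterion used by literature
mining services.

The *epilepsy pleiotropy rate* of a comorbidity is the percentage of genes
associated with the joint epilepsy-AND-comorbidity query among all
epilepsy-associated genes; rates are reported truncated (not rounded) to two
decimals, matching published convention.
"""

from __future__ import annotations

import json
import logging
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    InvalidQueryError,
    UndefinedBackgroundError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CorpusIndex",
    "DiseaseQuery",
    "GeneAssociationScore",
    "PleiotropyResult",
    "PrevalenceRecord",
    "RankCorrelation",
    "run_query",
    "relative_entropy_score",
    "associated_genes",
    "pleiotropy_rate",
    "prevalence_ratio",
    "correlate_rates",
]


@dataclass(frozen=True)
class CorpusIndex:
    """A document corpus with per-document disease-term and gene-symbol tags.

    Parameters
    ----------
    documents
        All document identifiers in the index.
    doc_diseases
        Mapping from document identifier to the set of disease-term
        identifiers tagged on it.  Keys must be a subset of ``documents``.
    doc_genes
        Mapping from document identifier to the set of gene symbols mentioned
        in it (uppercase).  Keys must be a subset of ``documents``.
    """

    documents: frozenset[str]
    doc_diseases: Mapping[str, frozenset[str]]
    doc_genes: Mapping[str, frozenset[str]]

    def __post_init__(self):
        docs = frozenset(self.documents)
        object.__setattr__(self, "documents", docs)
        object.__setattr__(
            self,
            "doc_diseases",
            {d: frozenset(v) for d, v in self.doc_diseases.items()},
        )
        object.__setattr__(
            self,
            "doc_genes",
            {d: frozenset(v) for d, v in self.doc_genes.items()},
        )
        for name, mapping in (("doc_diseases", self.doc_diseases),
                              ("doc_genes", self.doc_genes)):
            stray = set(mapping) - docs
            if stray:
                raise InvalidInputError(
                    f"{name} keys not in documents: {sorted(stray)[:5]}"
                )
        for doc, genes in self.doc_genes.items():
            for g in genes:
                if not g or g != g.upper():
                    raise InvalidInputError(
                        f"gene symbol {g!r} in {doc} must be non-empty uppercase"
                    )
        for doc, terms in self.doc_diseases.items():
            if any(not t for t in terms):
                raise InvalidInputError(f"empty disease term in {doc}")

    # -- convenience -------------------------------------------------------

    def genes(self) -> frozenset[str]:
        """All gene symbols mentioned anywhere in the corpus."""
        out: set[str] = set()
        for genes in self.doc_genes.values():
            out |= genes
        return frozenset(out)

    def diseases(self) -> frozenset[str]:
        out: set[str] = set()
        for terms in self.doc_diseases.values():
            out |= terms
        return frozenset(out)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CorpusIndex":
        """Read a corpus from TSV with columns ``document_id``,
        ``disease_terms`` and ``gene_symbols`` (semicolon-separated lists,
        empty cells allowed)."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                         comment="#")
        required = {"document_id", "disease_terms", "gene_symbols"}
        missing = required - set(df.columns)
        if missing:
            raise InvalidInputError(f"missing TSV columns: {sorted(missing)}")
        documents, doc_diseases, doc_genes = set(), {}, {}
        for row in df.itertuples(index=False):
            doc = row.document_id
            documents.add(doc)
            terms = frozenset(t for t in row.disease_terms.split(";") if t)
            genes = frozenset(g for g in row.gene_symbols.split(";") if g)
            if terms:
                doc_diseases[doc] = terms
            if genes:
                doc_genes[doc] = genes
        return cls(frozenset(documents), doc_diseases, doc_genes)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "document_id": doc,
                "disease_terms": ";".join(sorted(self.doc_diseases.get(doc, ()))),
                "gene_symbols": ";".join(sorted(self.doc_genes.get(doc, ()))),
            }
            for doc in sorted(self.documents)
        ]
        pd.DataFrame(rows, columns=["document_id", "disease_terms",
                                    "gene_symbols"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_json(cls, path: str | Path) -> "CorpusIndex":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            frozenset(payload["documents"]),
            {d: frozenset(v) for d, v in payload["doc_diseases"].items()},
            {d: frozenset(v) for d, v in payload["doc_genes"].items()},
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "documents": sorted(self.documents),
            "doc_diseases": {d: sorted(v)
                             for d, v in sorted(self.doc_diseases.items())},
            "doc_genes": {d: sorted(v)
                          for d, v in sorted(self.doc_genes.items())},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass(frozen=True)
class DiseaseQuery:
    """A single-term disease query or an AND-conjunction of disease terms."""

    terms: tuple[str, ...]
    combinator: str = field(default="")

    def __post_init__(self):
        terms = tuple(self.terms)
        object.__setattr__(self, "terms", terms)
        if not terms or any(not t for t in terms):
            raise InvalidQueryError("query needs >=1 non-empty disease term")
        expected = "single" if len(terms) == 1 else "and"
        combinator = self.combinator or expected
        if combinator != expected:
            raise InvalidQueryError(
                f"combinator {combinator!r} inconsistent with {len(terms)} term(s)"
            )
        object.__setattr__(self, "combinator", combinator)

    @classmethod
    def single(cls, term: str) -> "DiseaseQuery":
        return cls((term,))

    @classmethod
    def conjunction(cls, *terms: str) -> "DiseaseQuery":
        return cls(tuple(terms))


class GeneAssociationScore(NamedTuple):
    """Relative-entropy association of one gene with a query document set.

    ``relative_entropy`` is the single-gene Kullback-Leibler term
    ``p * ln(p / b)`` in nats, where ``p`` is the smoothed document frequency
    of the gene inside the query result and ``b`` the same over the
    background (corpus complement).  Its sign equals the sign of ``p - b``.
    """

    gene: str
    in_query_freq: float
    background_freq: float
    relative_entropy: float


@dataclass(frozen=True)
class PleiotropyResult:
    """Gene-overlap rate of one comorbidity against the index disease.

    ``rate_percent`` is ``100 * n_comorbidity_genes / n_index_genes``
    truncated toward zero at two decimals; ``rate_raw`` keeps the
    untruncated value.
    """

    comorbidity: str
    n_comorbidity_genes: int
    n_index_genes: int
    rate_percent: float
    rate_raw: float


@dataclass(frozen=True)
class PrevalenceRecord:
    """Prevalence of a condition in the index-disease population vs the
    general population, and their ratio."""

    condition: str
    prevalence_epilepsy: float
    prevalence_general: float
    prevalence_ratio: float


class RankCorrelation(NamedTuple):
    coefficient: float
    pvalue: float
    n: int
    unmatched: frozenset[str]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def run_query(index: CorpusIndex, query: DiseaseQuery) -> frozenset[str]:
    """Documents whose disease-term set contains *all* query terms.

    A single-term query returns the documents tagged with that term; an
    AND-query intersects, so adding terms never enlarges the result.
    """
    wanted = set(query.terms)
    return frozenset(
        doc for doc in index.documents
        if wanted <= index.doc_diseases.get(doc, frozenset())
    )


def relative_entropy_score(
    index: CorpusIndex,
    query_docs: Iterable[str],
    gene: str,
    pseudocount: float = 0.5,
) -> GeneAssociationScore:
    """Score one gene's enrichment in ``query_docs`` against the corpus rest.

    Document frequencies are smoothed symmetrically on both sides:
    ``p = (k + a) / (n + 2a)`` with pseudocount ``a``, so frequencies stay in
    (0, 1) and the score is finite.  Positive score <=> the gene is mentioned
    relatively more often inside the query result than outside it.
    """
    if pseudocount <= 0:
        raise InvalidInputError("pseudocount must be positive")
    qdocs = frozenset(query_docs)
    if not qdocs <= index.documents:
        raise InvalidQueryError("query_docs must be a subset of the corpus")
    background = index.documents - qdocs
    if not qdocs or not background:
        raise UndefinedBackgroundError(
            "relative entropy needs a non-empty query set and a non-empty "
            "corpus complement"
        )
    k_q = sum(1 for d in qdocs if gene in index.doc_genes.get(d, frozenset()))
    k_b = sum(1 for d in background
              if gene in index.doc_genes.get(d, frozenset()))
    p = (k_q + pseudocount) / (len(qdocs) + 2 * pseudocount)
    b = (k_b + pseudocount) / (len(background) + 2 * pseudocount)
    return GeneAssociationScore(gene, p, b, p * math.log(p / b))


def associated_genes(
    index: CorpusIndex,
    query: DiseaseQuery,
    pseudocount: float = 0.5,
) -> frozenset[str]:
    """Genes mentioned in >=1 query document with positive relative entropy."""
    qdocs = run_query(index, query)
    mentioned: set[str] = set()
    for doc in qdocs:
        mentioned |= index.doc_genes.get(doc, frozenset())
    return frozenset(
        g for g in mentioned
        if relative_entropy_score(index, qdocs, g, pseudocount).relative_entropy > 0
    )


def _trunc2(numerator: int, denominator: int) -> float:
    # exact integer truncation of 100*num/den at two decimals; avoids float
    # edge cases such as 10.5481... -> 10.54 (never 10.55)
    return (10000 * numerator // denominator) / 100.0


def pleiotropy_rate(
    n_comorbidity_genes: int,
    n_index_genes: int,
    comorbidity: str = "",
) -> PleiotropyResult:
    """Percentage of index-disease genes shared with a comorbidity query.

    The reported ``rate_percent`` is truncated toward zero at two decimals
    (e.g. 306/2901 -> 10.54, not 10.55).
    """
    if n_index_genes <= 0:
        raise InvalidInputError("n_index_genes must be positive")
    if n_comorbidity_genes < 0:
        raise InvalidInputError("n_comorbidity_genes must be >= 0")
    return PleiotropyResult(
        comorbidity=comorbidity,
        n_comorbidity_genes=n_comorbidity_genes,
        n_index_genes=n_index_genes,
        rate_percent=_trunc2(n_comorbidity_genes, n_index_genes),
        rate_raw=100.0 * n_comorbidity_genes / n_index_genes,
    )


def prevalence_ratio(
    prevalence_epilepsy: float,
    prevalence_general: float,
    condition: str = "",
) -> PrevalenceRecord:
    """Ratio of a condition's prevalence in the index-disease population to
    its prevalence in the general population."""
    if prevalence_epilepsy <= 0 or prevalence_general <= 0:
        raise InvalidInputError("prevalences must be positive")
    return PrevalenceRecord(
        condition=condition,
        prevalence_epilepsy=prevalence_epilepsy,
        prevalence_general=prevalence_general,
        prevalence_ratio=prevalence_epilepsy / prevalence_general,
    )


def correlate_rates(
    records: Sequence[PrevalenceRecord],
    rates: Sequence[PleiotropyResult],
) -> RankCorrelation:
    """Spearman rank correlation between prevalence ratios and pleiotropy
    rates, matched by condition identifier.

    Conditions present on only one side are excluded (and logged).  Needs at
    least three matched pairs.
    """
    by_condition = {r.condition: r for r in records}
    by_comorbidity = {r.comorbidity: r for r in rates}
    shared = sorted(set(by_condition) & set(by_comorbidity))
    unmatched = frozenset(set(by_condition) ^ set(by_comorbidity))
    if unmatched:
        logger.info("correlate_rates: excluding unmatched conditions %s",
                    sorted(unmatched))
    if len(shared) < 3:
        raise InsufficientDataError(
            f"need >=3 matched condition pairs, got {len(shared)}"
        )
    x = [by_condition[c].prevalence_ratio for c in shared]
    y = [by_comorbidity[c].rate_raw for c in shared]
    rho, p = stats.spearmanr(x, y)
    return RankCorrelation(float(rho), float(p), len(shared), unmatched)
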