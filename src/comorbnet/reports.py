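"""Report assembly: tabular outputs for each pipeline stage.

All tabular outputs are TSV with a leading ``#`` metadata header carrying
the tool version, a hash of the effective configuration, and the random
seed, so that any report can be traced back to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .corpus import (
    CorpusIndex,
    DiseaseQuery,
    associated_genes,
    pleiotropy_rate,
    run_query,
)
from .enrich import (
    ComparativeResult,
    SubgraphScore,
    normalize_label,
)

__all__ = [
    "config_hash",
    "metadata_header",
    "pleiotropy_table",
    "enrichment_table",
    "comparative_table",
    "summary_table",
    "write_tsv",
]


def config_hash(params: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def metadata_header(params: dict, seed: Optional[int] = None) -> list[str]:
    lines = [f"comorbnet {__version__}", f"config {config_hash(params)}"]
    if seed is not None:
        lines.append(f"seed {seed}")
    return lines


def write_tsv(df: pd.DataFrame, path: str | Path,
              header: Sequence[str] = ()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def pleiotropy_table(
    index: CorpusIndex,
    index_term: str,
    comorbidities: Sequence[str],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """One row per comorbidity: document and gene counts of the joint
    AND-query and the truncated pleiotropy rate, sorted by rate
    descending."""
    index_genes = associated_genes(index, DiseaseQuery.single(index_term),
                                   pseudocount)
    rows = []
    for disease in comorbidities:
        query = DiseaseQuery.conjunction(index_term, disease)
        docs = run_query(index, query)
        genes = associated_genes(index, query, pseudocount)
        result = pleiotropy_rate(len(genes), max(len(index_genes), 1),
                                 comorbidity=disease)
        rows.append({
            "disease": disease,
            "n_documents": len(docs),
            "n_disease_genes": len(
                associated_genes(index, DiseaseQuery.single(disease),
                                 pseudocount)),
            "n_comorbidity_genes": len(genes),
            "pleiotropy_rate": result.rate_percent,
        })
    df = pd.DataFrame(
        rows, columns=["disease", "n_documents", "n_disease_genes",
                       "n_comorbidity_genes", "pleiotropy_rate"])
    return df.sort_values(["pleiotropy_rate", "disease"],
                          ascending=[False, True], ignore_index=True)


def enrichment_table(
    scores: Sequence[SubgraphScore], selected: Sequence[str]
) -> pd.DataFrame:
    chosen = set(selected)
    rows = [
        {
            "label": s.label,
            "n_mapped": len(s.mapped_genes),
            "mapped_genes": ";".join(sorted(s.mapped_genes)),
            "coverage": round(s.coverage, 6),
            "specificity": round(s.specificity, 6),
            "score": round(s.score, 6),
            "hypergeom_p": s.hypergeom_p,
            "selected": s.label in chosen,
        }
        for s in sorted(scores, key=lambda s: (-s.score, s.label))
    ]
    return pd.DataFrame(
        rows, columns=["label", "n_mapped", "mapped_genes", "coverage",
                       "specificity", "score", "hypergeom_p", "selected"])


def comparative_table(result: ComparativeResult) -> pd.DataFrame:
    """Shared mechanisms with per-context scores, one row per shared
    normalized label."""
    a, b = result.contexts
    rows = [
        {
            "label": norm,
            f"score_{a}": round(result.score_pairs[norm][0], 6),
            f"score_{b}": round(result.score_pairs[norm][1], 6),
        }
        for norm in sorted(result.shared)
    ]
    return pd.DataFrame(rows,
                        columns=["label", f"score_{a}", f"score_{b}"])


def summary_table(summaries) -> pd.DataFrame:
    return pd.DataFrame(
        [s._asdict() for s in summaries],
        columns=["label", "n_entities", "n_relationships",
                 "n_connected_components", "n_citations"])
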