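"""Bundled reference counts from a published MEDLINE-scale epilepsy
comorbidity survey (SCAIView index of 2016-07-14).

For epilepsy and 22 comorbid conditions the survey reports, per MeSH disease
term: the number of retrieved documents, the number of genes with positive
relative entropy for the disease-specific query, the number of genes with
positive relative entropy for the joint epilepsy-AND-disease query, and the
epilepsy pleiotropy rate derived from the last count.

These numbers are *inputs* here: they let the pleiotropy arithmetic be
exercised at the published scale without re-running a literature service.
The printed rate of the Stroke row (17.78) is not consistent with its own
counts (100*633/2901 = 21.82); it is kept verbatim but flagged so that
consistency checks can exclude it.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "EPILEPSY_MESH_ID",
    "EPILEPSY_N_DOCUMENTS",
    "EPILEPSY_N_GENES",
    "DISCREPANT_CONDITIONS",
    "comorbidity_reference",
]

EPILEPSY_MESH_ID = "D004827"
EPILEPSY_N_DOCUMENTS = 192_245
#: total epilepsy-associated genes (positive relative entropy); the
#: denominator of every pleiotropy rate below
EPILEPSY_N_GENES = 2901

#: conditions whose printed rate disagrees with their own printed counts
DISCREPANT_CONDITIONS = frozenset({"Stroke"})

# condition, MeSH ID, documents, disease genes, comorbidity genes, printed rate (%)
_ROWS = [
    ("Stroke", "D020521", 210_846, 4533, 633, 17.78),
    ("AD", "D000544", 109_495, 4968, 396, 13.65),
    ("Migraine", "D008881", 30_928, 1230, 306, 10.54),
    ("PD", "D010300", 79_103, 3646, 258, 8.89),
    ("Hypertension", "D006973", 391_190, 5574, 252, 8.68),
    ("Dementia", "D003704", 183_802, 5833, 220, 7.58),
    ("Diabetes mellitus", "D003920", 394_411, 6661, 184, 6.34),
    ("Intestinal diseases", "D007410", 629_691, 9093, 166, 5.72),
    ("Thyroid diseases", "D013959", 153_025, 4366, 133, 4.58),
    ("Anxiety", "D001007", 84_138, 1782, 124, 4.27),
    ("Arthritis", "D001168", 259_327, 5367, 122, 4.2),
    ("Cataract", "D002386", 52_150, 2238, 119, 4.1),
    ("Asthma", "D001249", 147_697, 3761, 86, 2.96),
    ("Glaucoma", "D005901", 56_679, 2303, 48, 1.65),
    ("Depressive disorder, major", "D003865", 15_706, 1249, 46, 1.58),
    ("Urinary incontinence", "D014549", 34_170, 720, 24, 0.82),
    ("Peptic ulcer", "D010437", 68_234, 1445, 21, 0.72),
    ("Back pain", "D001416", 48_516, 1191, 17, 0.58),
    ("Pulmonary disease, chronic obstructive", "D029424", 35_627, 2244, 15, 0.51),
    ("Fibromyalgia", "D005356", 9021, 468, 10, 0.34),
    ("Emphysema", "D004646", 25_511, 1261, 9, 0.31),
    ("Bronchitis, chronic", "D029481", 9085, 580, 2, 0.06),
]


def comorbidity_reference() -> pd.DataFrame:
    """The reference table as a DataFrame (one row per comorbid condition).

    Columns: ``condition``, ``mesh_id``, ``n_documents``,
    ``n_disease_genes``, ``n_comorbidity_genes``, ``printed_rate_percent``.
    """
    return pd.DataFrame(
        _ROWS,
        columns=[
            "condition",
            "mesh_id",
            "n_documents",
            "n_disease_genes",
            "n_comorbidity_genes",
            "printed_rate_percent",
        ],
    )
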