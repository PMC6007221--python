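"""Literature co-occurrence pleiotropy: published counts and a synthetic
comorbidity query.

Recomputes epilepsy pleiotropy rates from the bundled published comorbidity
count table, then simulates a small tagged literature index with genes
planted for the joint epilepsy-AND-migraine context and recovers them via
the positive-relative-entropy association call.
"""

from comorbnet import (
    CorpusSimConfig,
    DiseaseQuery,
    associated_genes,
    correlate_rates,
    pleiotropy_rate,
    prevalence_ratio,
    simulate_corpus,
)
from comorbnet.corpus import PrevalenceRecord
from comorbnet.reference import EPILEPSY_N_GENES, comorbidity_reference

# -- published arithmetic ---------------------------------------------------
df = comorbidity_reference()
print("epilepsy pleiotropy rates recomputed from published counts")
print("(percentage of the 2901 epilepsy-associated genes shared with the")
print(" joint epilepsy-AND-comorbidity literature query, truncated):")
for condition in ("AD", "Migraine", "PD", "Dementia", "Diabetes mellitus"):
    n = int(df.loc[df.condition == condition, "n_comorbidity_genes"].iloc[0])
    rate = pleiotropy_rate(n, EPILEPSY_N_GENES, condition)
    print(f"  {condition:20s} {n:4d}/{EPILEPSY_N_GENES} -> "
          f"{rate.rate_percent:5.2f}%")

rec = prevalence_ratio(5.71, 3.47, "Migraine")
print(f"\nmigraine prevalence ratio (epilepsy vs general population): "
      f"{rec.prevalence_ratio:.3f}")

# -- synthetic recovery -----------------------------------------------------
planted = frozenset({"G0001", "G0002", "G0003", "G0004"})
config = CorpusSimConfig(
    planted={("epilepsy", "migraine"): planted}, seed=11)
index, truth = simulate_corpus(config)
query = DiseaseQuery.conjunction("epilepsy", "migraine")
found = associated_genes(index, query)
print(f"\nsynthetic corpus: {len(index.documents)} documents, "
      f"{len(planted)} genes planted 10x in the joint context")
print(f"recovered planted genes with positive relative entropy: "
      f"{len(found & planted)}/{len(planted)}")
print("(positive relative entropy = mentioned relatively more often inside"
      " the query result than in the rest of the corpus)")

# -- rank correlation -------------------------------------------------------
records = [PrevalenceRecord(c, 2.0 + i, 2.0, (2.0 + i) / 2.0)
           for i, c in enumerate(("a", "b", "c", "d", "e"))]
rates = [pleiotropy_rate(10 * (5 - i), 100, c)
         for i, c in enumerate(("a", "b", "c", "d", "e"))]
res = correlate_rates(records, rates)
print(f"\nSpearman rho between prevalence ratios and pleiotropy rates on a "
      f"toy anti-monotone pairing: {res.coefficient:.2f} "
      f"(p={res.pvalue:.3f}, n={res.n})")
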