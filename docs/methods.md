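# Methods

## Literature co-occurrence model

The corpus layer models a disease/gene-tagged document index at
presence/absence granularity: each document carries a set of disease-term
identifiers and a set of gene symbols. Disease queries are either a single
term or an AND-conjunction (a document matches iff it carries *all* terms),
so adding a term can never enlarge a result set.

**Association criterion.** A gene is associated with a query when (a) it is
mentioned in at least one query document and (b) its relative entropy is
positive. We implement the single-gene Kullback–Leibler term on document
frequencies,

    RE(g) = p · ln(p / b),   p = (k_q + a) / (n_q + 2a),   b = (k_b + a) / (n_b + 2a),

where `k_q`/`k_b` count query/background documents mentioning the gene,
`n_q`/`n_b` are the set sizes, and `a` is a symmetric pseudocount
(default 0.5, keeping both frequencies in (0, 1) and the score finite).
The background is the corpus complement of the query result, not the whole
corpus. Only the *sign* of the score feeds the association call, and with
symmetric smoothing the sign provably equals the sign of `p − b`.
Document-level presence/absence (rather than mention counts) is the
simplest model consistent with "co-occurring in the literature"; mention
frequency, MeSH-hierarchy expansion and named-entity recognition are out
of scope.

**Calibration caveat.** A sign criterion is a coin flip under the null: a
gene with identical true frequency on both sides is called positive with
probability ≈ ½ (smoothing nudges it slightly above, since the query side
is smaller). The criterion therefore does *not* control a false-positive
rate; it is a recall-oriented filter whose practical selectivity in
MEDLINE-scale indices comes from most genes never being mentioned in a
query's documents at all. The synthetic null calibration in the test suite
measures this honestly (≈ 50% of the vocabulary is called associated when
every gene is null and mentioned at baseline rate); a calibrated
alternative would require a significance test, which would no longer be
the sign-only criterion this layer models.

**Pleiotropy rate.** `100 · n_comorbidity_genes / n_index_genes`,
*truncated* toward zero at two decimals (integer arithmetic:
`(10000·n // d) / 100`), because the published two-decimal values are
truncations, not roundings (e.g. 306/2901 → 10.5481… prints as 10.54).
The raw float is retained alongside. One row of the bundled 22-row
reference table (Stroke: 633/2901 printed as 17.78 instead of 21.82) is
internally inconsistent; it is flagged in `comorbnet.reference` and
excluded from consistency checks.

**Prevalence correlation.** Spearman rank correlation (two-sided) between
prevalence ratios and pleiotropy rates over conditions matched by
identifier, requiring ≥ 3 matched pairs; unmatched conditions are excluded
and logged. Spearman is chosen because the relationship of interest is
monotone association between two ratio scales with no distributional
model.

## Knowledge-assembly model

Entities are `(function, namespace, name)` triples over seven functions
(abundance, protein, gene, rna, bioprocess, pathology, complex); relations
are a *multiset* of typed statements (five causal kinds: increases,
directly_increases, decreases, directly_decreases, regulates; three
associative) each carrying a `(citation type, identifier)` pair, optional
evidence text, and a set of mechanism (subgraph) labels. Multi-edges from
different citations count separately, consistent with relation-level
curation.

The supported BEL dialect is deliberately minimal: simple one-argument
terms, the eight relations (keyword or arrow shorthand), and
`SET`/`UNSET` for Citation, Evidence and Subgraph. Nested terms, protein
modifications and variants raise a parse error with the line number rather
than degrade silently; a lenient mode skips and counts such lines so that
externally curated files with richer syntax can still be ingested
partially. `serialize → parse` is an isomorphism on the dialect (relation
multiset, label inventory); isolated entities have no statement form in
BEL script and round-trip through the node-link JSON serialization
instead, which orders entities lexicographically and relations by curation
order.

Per-mechanism summaries report entities, relations, connected components
on the **undirected** projection (a "connected group of nodes" is
direction-free), and distinct citations; the Total row de-duplicates
citations across mechanisms, so it is at most the per-label sum.

## Mechanism enrichment

Seed genes (a drug's targets) map to a mechanism iff some gene/RNA/protein
entity of the induced subgraph carries the symbol under a gene-symbol
namespace (HGNC and a plain `SYMBOL` namespace by default; configurable),
case-insensitively. Per mechanism:

* coverage = mapped / seeds present anywhere in the assembly,
* specificity = mapped / gene-like entities in the mechanism,
* score = geometric mean √(coverage · specificity) ∈ [0, 1],
* hypergeometric upper tail P(X ≥ mapped) drawing the mechanism's
  gene-like entities from the assembly's gene universe (scipy).

The score is intentionally *relative* — the workflow it models publishes
only relative enrichment scores — so mechanisms are selected by empirical
percentile over the candidates with ≥ 1 mapped gene: threshold = the
(1 − fraction)-quantile with linear interpolation, ties at the threshold
included, never empty when candidates exist. With 12 distinct-score
candidates and fraction 0.10 this yields exactly 2 selections, the
published selection shape. When hunting k planted mechanisms among n
candidates in simulations we set fraction ≈ k/n (e.g. 0.25 for 2 of 8),
since the decile rule over 8 candidates arithmetically selects only the
top 1. The hypergeometric tail is reported alongside as a calibrated
companion but does not drive selection.

Comparative enrichment scores and selects independently per context and
intersects by normalized label (lowercased, trailing
"subgraph"/"sub-graph" stripped), reporting score pairs for shared labels.

## Subnetwork extraction

Paths are unweighted and directed over causal edges only by default
(association/correlation edges do not form mechanism chains); relation
polarity is carried as metadata but does not affect length, since no
weighting scheme is part of the model. For every (source, sink) pair *all*
tied shortest paths are enumerated (networkx) and unioned — merging paths
into a graph presupposes keeping ties; a single-path mode exists by flag.
Unreachable pairs are recorded; an optional undirected-fallback retries
them on the undirected projection and flags the result. Missing sources or
sinks are reported, and only an entirely missing side is an error.

A **common upstream controller** is a node outside the subnetwork with
direct (1-hop) causal out-edges onto on-path nodes of ≥ 2 distinct
(source, sink) pairs — the minimal reading of "common upstream
controller"; the hop depth is configurable, in which case intermediate
nodes of the connecting shortest causal chains are added too. Controller
augmentation never removes anything and never changes registered path
lengths. The extraction stops at the merged path+controller graph; manual
interpretation and simplification of the result is explicitly not
automated.

## Synthetic data

`simulate_corpus` draws documents in strata (background, one disease, one
disease pair) and mentions each vocabulary gene independently per document
with baseline probability 0.02, boosted to `factor × baseline` for genes
planted in the document's exact disease context. Defaults (600 background,
200 index-disease, 120 comorbidity and 60 joint documents; 300 genes;
factor 10) represent a study slice in which a 200-document query must
separate ten-fold enriched genes from baseline mentions. What it does
*not* emulate: MEDLINE's scale, heavy-tailed gene mention frequencies,
correlated mentions within topics, or noisy entity tagging — so passing
recovery tests show the scoring machinery is correct under the stated
model, not that the criterion is well-calibrated on real literature (see
the calibration caveat above).

`simulate_assembly` builds eight mechanism blocks (12 protein entities + 3
bioprocesses each; within-block edge probability 0.25, between-block 0.02,
10% of edges associative) with 10 seed genes included in each block with
probability 0.05 (non-planted) vs 0.6 (planted, enrichment 12×); each
block is guaranteed ≥ 1 seed so that all blocks are enrichment candidates,
mirroring workflows restricted to mechanisms with at least one mapped
gene. Cross-block edges carry *no* mechanism label — a relation bridging
two mechanisms is annotated to neither — keeping mechanism membership
block-local. Planted source→sink chains are kept shortest
**constructively**: random edges are never aimed at chain nodes, so every
route into a chain's sink must traverse the chain; minimality is
re-verified on the emitted graph. The optional planted controller feeds
interior nodes of two chains and is excluded from random wiring, making
exact recovery well-defined. Fixed seeds give byte-identical serialized
output.

## Numerical and degenerate-input choices

* Truncation uses exact integer arithmetic (no float rounding edge cases).
* Hypergeometric tails use `scipy.stats.hypergeom.sf(k−1, M, K, n)`;
  k = 0 gives probability 1.
* A mechanism with zero gene-like entities has specificity 0 and score 0;
  score is 0 iff no seed maps.
* Quantile thresholding uses numpy's linear-interpolation quantile;
  all-equal scores select everything.
* Empty query or whole-corpus query ⇒ undefined-background error; empty
  seed sets, non-positive prevalences and denominators are rejected.
* Path queries require disjoint, non-empty source and sink sets.

## Test-suite problem sizes

Property tests run tens of hypothesis examples; oracle comparisons use
200 random ≤ 10-node digraphs and exhaustive hypergeometric enumeration up
to 12-gene universes; recovery experiments use 100 seeded replicates of
the default generator configurations. The full suite and the acceptance
script each complete in well under a minute on one CPU.

## Known limitations

* The BEL dialect covers entity-level causal curation only — no nested
  statements, namespaces are not resolved against terminology servers.
* The enrichment score is a design choice standing in for a
  server-internal relative score; absolute score values (and any published
  absolute threshold) are therefore not comparable, only rankings are.
* The controller definition is one of several defensible readings of
  "common upstream controller"; alternatives (shared ancestors at depth
  > 1 by default, polarity-consistent regulators) are not explored.
* The association criterion's null behaviour (see calibration caveat)
  means corpus-layer gene lists should be read as recall-oriented
  candidates, not significance-controlled calls.
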