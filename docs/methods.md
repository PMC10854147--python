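# Methods notes

This note records the model, the defaults and the judgement calls behind
`gsthemes`, in the spirit of a statistical package's methods appendix.

## Similarity over the measured-gene universe

All pairwise similarities are computed over the *universe* — the n genes
measured in the experiment — never over the raw database sets: a gene-set
is first intersected with the universe, and the contingency table's
`n00` cell counts genes measured but in neither set. The choice of universe
therefore changes ARI (which uses all four cells) but not Jaccard or the
overlap coefficient (which ignore `n00`). When the caller supplies no
universe, the union of all set members is used so the tool degrades
gracefully, but an explicit measured-gene list is always preferable and the
CLI accepts one (`--universe`).

Binomial coefficients in the ARI are evaluated in exact integer arithmetic
(`math.comb`) and only the final ratio is floating point; this keeps the
measure exact to machine precision for universes of any realistic size.
Degenerate ARI denominators (both partitions trivial: empty vs empty, or
full vs full universe) return 1 when the partitions are identical and 0
otherwise, matching the convention of standard adjusted-Rand
implementations. Jaccard of two empty sets is 0; the overlap coefficient
with an empty set is 0.

Empty-after-restriction sets are retained in the collection and flagged,
but excluded from the similarity matrix — silently dropping them would hide
data problems, while including them would force a similarity convention on
pairs with no information.

## Overlap graph

An edge requires `sim >= threshold` **and** `sim > 0`. The weak inequality
keeps boundary pairs (a `--strict` switch gives `>`); the positivity
requirement makes "threshold 0" mean "any overlap" rather than "complete
graph", and guarantees positive random-walk weights. Default measure ARI
with threshold 0.25; empirically useful thresholds sit around 0.2–0.4,
lower values giving denser graphs and broader, less specific themes.
Isolated gene-sets are dropped before clustering and reported in the output
bundle — they are outside the theme analysis but may still matter to the
study.

## Theme detection and ordering

Community detection is delegated to python-igraph's walktrap
(Pons–Latapy): agglomerative merging by short random-walk distance, walk
length 4 (the reference default; exposed as `steps`), with similarity
values as transition weights and the merge tree cut at maximum modularity.
The result is deterministic for a fixed graph; cluster ids are assigned by
each cluster's lexicographically smallest member, so input order and
relabelling cannot change the output. Components never merge, since no
walk crosses between them. An edgeless (but non-empty) graph yields all
singletons; an empty graph yields an empty partition.

Ordering uses the product of ranks: size rank (1 = largest, ties share the
minimum rank) times median-statistic rank (1 = best under the caller's
`direction`; `use_absolute` ranks |median| for signed two-sided
statistics). Missing medians are imputed as the worst rank. Rank-product
ties break by the better statistic rank, then by cluster id — a documented
total order so outputs are bit-reproducible. The statistic column is
whatever the caller supplies; p-value-like statistics should be passed
−log10-transformed or with `direction='smaller-better'`.

## Text annotation

Tokenisation follows gene-set naming conventions: split on `_ / @ ( ) |`
and whitespace, strip punctuation, lowercase, drop purely numeric tokens,
English stop words (scikit-learn's built-in list, swappable) and excluded
words, then lemmatise and re-apply the exclusions (so a plural of an
excluded word cannot resurface). The packaged exclusion list
(`data/exclusions.txt`, user-replaceable) holds database prefixes/suffixes
— kegg, reactome, hallmark, gobp, wp, ... — and deliberately keeps
informative generic words (pathway, signaling, regulation). Lemmatisation
is a compact rule-based English inflection stripper (regular plurals plus
an irregulars dictionary); gene-set vocabularies are controlled enough
that this matches a full dictionary lemmatiser on the words that matter.

IDF uses the natural log by default (`idf = ln(N/df)`, so idf = 0 exactly
when a term occurs in every corpus document); base 2 is available and the
base is recorded. tf is the raw count in the cluster's concatenated
document (a relative-frequency mode exists but is off by default). The
reference corpus should be the full database the sets came from; when only
the analysed collection is available it serves as its own corpus, which
weakens but does not invalidate the weighting. Terms absent from the
corpus are scored at df = 1 (maximal idf) and flagged `novel`. Up to 25
top terms are kept per cluster, ties broken alphabetically.

## Gene tables and PPI context

Gene frequency counts member sets containing each gene, on
universe-restricted sets, so Σ frequencies = Σ restricted set sizes per
cluster. The joined table is sorted by frequency then |statistic| as a
convenience ranking of "explanatory" genes; the interpretation, not the
ranking, is the substance.

PPI cleaning combines duplicate unordered pairs by maximum confidence
(associative and commutative, hence order-independent and idempotent),
drops self-edges, and — in the PSI-MI TAB dialect — keeps only records
whose two interactors share a taxid. Ortholog inference maps both
endpoints through a two-column table (one-to-many allowed), flags the
result `inferred`, and merges with native edges by the same max rule,
native flag winning ties. Degree filtering is single-pass: degree is
computed once on the confidence-filtered induced graph, nodes below
`min_degree` are removed with their edges, and nodes thereby isolated are
removed too; there is no iteration to a fixpoint, so the filter is a
one-shot, reproducible operation rather than a k-core. Identifier
namespaces are the caller's responsibility (a PSI-MI id is taken as the
text after the first colon); map to your gene ids upstream.

## Factor-loading scoring

Genes are ranked ascending by loading with mid-rank ties; a set's score is
`(mean member rank − (m+1)/2)/(n − m) − 0.5`, the unidirectional centred
rank score bounded in [−0.5, 0.5] with ±0.5 attained exactly at the
top-/bottom-m configurations. Only ranks enter, so the score is invariant
under strictly monotone transforms of the loadings and antisymmetric under
negation. Sets with m = 0 or m = n are flagged unscorable. Selection uses
a strict |score| > 0.2 default; the factorisation itself (PCA or
otherwise) is out of scope — the module consumes any loading vector.

## Synthetic generator

The generator plants K themes over an n-gene universe: disjoint gene pools
of size P (a `pool_overlap` fraction shares genes between adjacent themes
to emulate correlated processes), s sets per theme each sampling ⌈f·P⌉
pool genes plus q uniform background genes, names of the form
`KEYWORD_FILLER_FILLER_j` from packaged lemma-stable vocabulary, per-gene
statistics Normal(theme mean, 0.5) for pool genes and Normal(0, 0.5) for
background, theme means alternating in sign with magnitudes from 3 down to
1, and per-set statistics as member means. Defaults (n = 5000, K = 5,
s = 20, P = 150, f = 0.4, q = 10) put within-theme ARI near 0.35 and
between-theme ARI near 0 — overlapping but non-identical sets, cleanly
separated themes. A single seeded NumPy generator drives every draw, so
spec + seed reproduces the collection bit for bit.

What the generator does *not* emulate: the hierarchical parent–child
structure of real ontologies (which the overlap coefficient targets),
heavy-tailed set-size distributions, shared genes across many unrelated
sets, and inconsistent naming vocabularies. Passing the planted-recovery
tests therefore shows the pipeline machinery is correct, not that real
databases decompose into K clean themes; on real inputs, theme granularity
is governed by the similarity threshold, and thresholds should be explored
in the 0.2–0.4 band.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale: 500 random pairs over a
2000-gene universe for oracle equivalence, 50 random matrices for graph
recounts, 20 generator seeds (100 sets × 5000 genes each) for recovery
medians, 1000 random sets for scoring bias. These sizes give stable
medians and sub-minute runtimes; all randomness flows from explicit seeds
and every pipeline stage is deterministic given its inputs.

## Known limitations

- Walktrap is the only built-in clustering; the partition interface is the
  extension point for alternatives (Louvain, MCL).
- The exclusion list is an editorial default; domain-specific prefixes
  (e.g. consortium names) should be added by the user.
- The PSI-MI TAB reader parses a pragmatic 2.5 subset (id, taxid,
  confidence columns); exotic exporter conventions may need the TSV path.
- Pairwise similarity is O(k²) in the number of sets with an exact-integer
  ARI per pair; collections of a few thousand sets are fine, tens of
  thousands are not the target.
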