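# Methods

## Model

### Hypergeometric pair scoring

Every (lncRNA, disease) pair in the cross product of interaction-annotated
lncRNAs and association-annotated diseases is scored by the overlap of
their miRNA partner sets. The miRNA universe N is the union of miRNAs
appearing on either side — miRNAs attached only to lncRNAs or only to
diseases still dilute the overlap and belong in the universe. The p-value
is the inclusive upper tail P(X ≥ x) of Hypergeometric(N, M, L): the
inclusive convention is the standard enrichment choice and makes x = 0
give p = 1 exactly, so pairs with no shared miRNA carry no signal rather
than an artifactual one. A strict-tail variant (P(X > x)) is available via
the `tail="gt"` option for sensitivity analysis.

The tail is evaluated with `scipy.stats.hypergeom.sf`, which works with
log-gamma binomial coefficients and is stable well beyond the ~10^4-miRNA
scale this model meets. Overlap counts for all pairs come from one product
of binary incidence matrices, so the full cross product (hundreds of
thousands of pairs at the scale of the public catalogs) scores in seconds.

Multiple testing is controlled by Benjamini–Hochberg applied **jointly to
all pairs** (not per disease): the procedure is one family of hypotheses
and joint adjustment keeps FDR comparable across diseases. The step-up
formula q(i) = min_{j ≥ i} m·p(j)/j is implemented directly (sorted
p-values, reverse running minimum, clipped at 1); a unit test cross-checks
it against `statsmodels.stats.multitest.multipletests(method="fdr_bh")`.
Calling uses FDR strictly below 0.05 by default.

Assumptions worth stating: edges are treated as exchangeable draws — the
test ignores miRNA degree heterogeneity, so hub miRNAs inflate overlap for
every pair they touch; and p-values of pairs sharing a lncRNA or disease
are dependent, which BH tolerates (PRDS-type dependence) but does not
model.

### Leave-one-out evaluation

Each gold association is ranked by ascending p-value against the candidate
set: all scored pairs not in the gold standard. Other held-out positives
are excluded from the candidates — they carry evidence and would otherwise
be counted as false positives. Because scoring uses no gold information,
leaving one association out changes no score, and the leave-one-out loop
reduces to ranking each positive once; the literal per-fold loop is kept
behind `literal_folds=True` and tested to agree exactly. Ties between a
test and candidate score count one half (Mann–Whitney convention), making
the rank-based AUC identical to the trapezoidal integral of the ROC curve
built from the pooled scores (`sklearn.metrics.roc_curve`). A
`per_disease=True` mode ranks each positive only among candidates of its
own disease, pooling normalized ranks; it exists for sensitivity analysis,
the global ranking being the primary protocol.

### Disease semantics and the similarity cascade

A disease's DAG is the ancestor closure of its MeSH term(s) under the
parent→child term graph. Contributions: 1 at the disease's own terms,
otherwise Δ · max over the node's children inside the DAG, computed in
reverse topological order. Δ defaults to 0.5 — the customary decay for
this family of DAG-contribution measures — and is configurable
(`--delta`); no relation-type edge weighting is applied. A disease with
several tree positions gets one merged DAG with the max contribution per
node, which keeps contributions in (0, 1] and the recursion well defined.
Similarity is the shared contribution mass over the summed semantic
values; it is 1 exactly for identical DAGs and 0 for disjoint ones.

The cascade applies best-match-average twice: S2(u, v) over miRNA disease
groups with base S1, then FS(i, j) over lncRNA miRNA groups with base S2.
The element–group step is the best match (max); a `combiner="mean"` option
exposes the averaged alternative without changing the default. Annotations
absent from the base matrix are dropped with a logged count rather than
imputed as zero (zero-imputation would bias S2/FS downward), and entities
left with empty groups are excluded from the output: the cascade is
undefined for lncRNAs without known miRNA partners. Diagonals are forced
to exactly 1 to avoid float drift on identical groups.

## Synthetic data

The generator emulates the three association tables: independent
Bernoulli background edges at density 0.05 in both bipartite layers, plus
planted pairs wired to `n_shared` common miRNAs on top of the background
(plants only add edges, so the planted overlap is guaranteed). Defaults —
50 miRNAs, 20 diseases, 30 lncRNAs, density 0.05, one plant with 10 shared
miRNAs — are the study conditions used across the tests and the acceptance
script; at these settings the planted pair's tail probability is ~10^-7
against background coincidences of ~10^-3. The DAG generator builds a
complete b-ary tree of the requested depth with occasional extra
same-level parents (a genuine DAG, acyclic by construction) and maps each
disease to one leaf.

What the fixtures do **not** emulate: the heavy-tailed degree
distributions of real CLIP-seq and literature-curated networks, correlated
disease groups, miRNA family structure, and naming noise across databases.
Passing the planted-recovery tests therefore demonstrates the machinery
(correct tail, correct FDR, correct ranking), not the field performance of
the model on real catalogs; the reference-dataset reproduction path exists
for that and activates when the third-party tables are supplied.

All randomness flows from a single integer seed through one
`numpy.random.Generator`; identical seeds give byte-identical fixture
files.

## Preprocessing rules

Duplicate association rows (same pair, different evidence) collapse to
one edge. miRNA genomic copies merge by stripping a trailing `-<digit>`
suffix only when the remaining stem itself ends in a numbered segment
(`hsa-mir-125b-1` → `hsa-mir-125b`, but `hsa-mir-21` untouched); the
pattern is configurable and the merge is idempotent. Entity labels are
trimmed, case-folded and whitespace-collapsed; an optional alias TSV maps
residual disease-name synonyms between source databases. Gold associations
are filtered to diseases and lncRNAs present in the two input networks
before evaluation.

## Numerical choices and degenerate inputs

- Ranking tie-break: p-value ascending, then larger shared count x, then
  lexicographic label — deterministic output with no hidden state.
- Pairs whose lncRNA or disease has zero miRNA partners (possible when
  entity lists are supplied explicitly) score x = 0, p = 1 instead of
  being dropped, keeping the score matrix complete for ranking.
- Empty miRNA universe, empty annotation groups, cyclic term graphs and
  unmapped diseases raise explicit errors (or logged exclusions where the
  rest of the computation is still well defined).
- Brute-force oracles (draw enumeration for the tail, double-loop BMA,
  concordance counting for AUC) guard their instance sizes and live in the
  fixtures module; they are test-only references, never the computation
  path.

## Problem sizes

The test suite and acceptance script use the fixture defaults above;
planted-recovery statistics aggregate 100 seeds, oracle-agreement sweeps
use exhaustive enumeration for all universes N ≤ 12 and hundreds of random
vectors/groups. The whole suite and the acceptance script each run in
seconds on one CPU; full scoring of the public catalogs (~1100 lncRNAs ×
~380 diseases) takes seconds as well thanks to the vectorized incidence
product.

## Known limitations

- The hypergeometric null ignores degree heterogeneity; a
  degree-preserving permutation null is out of scope.
- The cascade inherits the bias noted for group-based similarity: lncRNAs
  with more miRNA partners, or partners annotated to more diseases, tend
  toward higher similarity.
- Disease-name reconciliation across databases is normalization plus an
  optional alias table; no ontology mapping is attempted.
- MeSH XML descriptor parsing is out of scope; DAG inputs are plain
  two-column TSVs.
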