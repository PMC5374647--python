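# Methods

## Overview

`oncothemes` re-expresses tumor mutation profiles in a semantic space and
discovers subtypes there. The pipeline has six stages — SGA calling, gene
word vectors, tumor documents, nHDP topic modeling, consensus clustering,
survival stratification — each implemented as an independent module with
file-level inputs and outputs, orchestrated by `oncothemes.pipeline`.

## SGA calling

A tumor–gene pair is an SGA event if either channel fires:

* **Mutation channel.** Frame-shift, nonsense, splice-site and
  multi-nucleotide variants are always functional; missense variants only
  when labelled `probably_damaging` or `possibly_damaging` by an upstream
  impact predictor. Missense without a damaging label, and any class outside
  the enumerated set (e.g. silent), are excluded: the filter enumerates
  inclusions, everything else falls through.
* **Copy-number channel.** Only GISTIC states ±2 are candidates. For each
  gene, the copy-neutral samples (no CNV call of any magnitude) define a
  normal reference via their sample mean and unbiased variance (n−1); the
  candidate's expression is tested one-tailed in the direction that
  corroborates the copy-number change — upper tail for amplification, lower
  for deletion — and kept if p < 0.01. Direction-concordance is the only
  biologically coherent reading of a one-tailed test here. Genes with fewer
  than two neutral samples, zero reference variance, or no expression row
  are skipped with a logged warning rather than failing the run. Expression
  values are used on the scale provided; no transformation is applied.

The two channels are unioned into a binary matrix; genes altered in fewer
than `min_recurrence` tumors (default 20, the value appropriate for a
multi-thousand-tumor cohort) are dropped as probable passengers. Recurrence
is counted over the combined cohort after the union. Tumors left with no
events are retained (they become empty documents downstream) and logged.

## Gene word vectors

Text preprocessing: lower-case, split on any non-alphanumeric character,
keep tokens of length ≥ 2 or containing a digit (so "p53" survives), remove
stop words (a fixed English list packaged with the library, for
determinism), then Porter-stem. The stemmer is the classic 1980 algorithm
implemented in-package; tokens containing digits pass through unchanged,
which also makes the synthetic generator's token universe stemmer-stable.

tf-idf uses the gene corpus: `tfidf(w,d,D) = tf(w,d) · log10(|D|/df(w,D))`
with |D| the number of gene documents — the entire list of genes is treated
as one large corpus at this stage; tumors only become the documents later,
when the topic model is fit. The global vocabulary keeps the `vocab_size` (default 20,000) tokens
with the highest cumulative tf-idf, ties broken lexicographically — a
deterministic tie-break is required for reproducibility and the choice of
lexicographic order is arbitrary but fixed.

Each gene document stores **both** integer token counts and real tf-idf
scores. Ranking, truncation to the top `vector_size` (default 200) tokens
and alias boosting operate on tf-idf; the downstream bag-of-words uses the
integer counts, because the topic model's likelihood is defined over
counts. Alias boosting sets each alias token's tf-idf (and, mirroring it,
its count) to the maximum over the selected vector, inserting the alias if
absent and evicting the lowest-ranked non-alias token when at capacity.
Selection happens first, boosting second. Aliases are matched after the
same preprocessing as ordinary text, and only when the alias token actually
occurs in the gene's text and survives vocabulary restriction.

## Tumor documents

A tumor's document is the token-wise sum of the selected (boosted) counts
of its altered genes. Genes without usable text are skipped and logged;
empty documents are retained in the corpus, excluded from model fitting,
and assigned a uniform allocation over the allocated topics afterwards.

## nHDP topic model

The truncated tree has branching (10, 5, 3) below the root — 211 candidate
topics. Generatively: topic-word distributions φ_t ~ Dirichlet(β₀ = 0.01);
per document, a truncated stick-breaking draw (Beta(1, α), α = 1) over the
children of every internal node selects subtrees, and a per-node switch
U ~ Beta(1, 1) lets words stop at internal nodes; a word's topic is the
node where its path stops.

Inference is full-batch mean-field coordinate ascent: per-token-type
responsibilities over all 211 nodes, closed-form Beta updates for the
document sticks and switches, Dirichlet updates for the topics. Every
update is an exact coordinate maximization, so the evidence lower bound is
non-decreasing across iterations — the property the sanity tests assert
(with 1e-6 relative slack for floating-point noise). Iteration stops when
the relative ELBO change falls below `tol` (default 1e-5) or at
`max_iters`. The reported `log_likelihood` is the final ELBO (the
cumulative variational document likelihood); `theta[d]` is the expected
fraction of document d's words allocated to each node.

**Initialization** is hierarchical k-means down the tree: documents are
row-normalized, the root takes the corpus mean, each internal node splits
its assigned documents into as many k-means clusters as it has children,
and each child topic starts at its cluster centroid (smoothed 10% toward
the corpus frequencies); unreached nodes are seeded from random documents.
A corpus-frequency-plus-noise initialization was tried first and regularly
lost planted child topics to mode collapse (matched cosines 0.5–0.65 on the
planted-tree corpus); the k-means scheme — also the strategy of reference
nHDP implementations — recovers them at ≈ 0.99 for every seed tried, so it
is the default and only initialization.

`best_of_k` fits k models with consecutive seeds and keeps the highest
ELBO, logging all k likelihoods (default k = 10 for real-data scale).
"Allocated" topics are nodes whose theta mass exceeds a threshold in at
least one fitted document.

Stochastic (minibatch) inference was deliberately not implemented: at the
corpus sizes this package targets, one full-batch fit takes well under a
minute, and full-batch coordinate ascent carries the monotonicity guarantee
the tests rely on.

## Gene-topic mapping

`p(g|t) ∝ Σ_d Σ_w count(w|g)·φ_t(w)·θ_d(t)`, normalized over genes within
each topic (the notation p(g|t) dictates normalizing over g for fixed t).
The document sum runs over *all* documents, following the unconditional
form of the defining expression; restricting d to tumors carrying g is a
plausible alternative that is not used. The triple sum factorizes into
(count @ φᵀ) · Σ_d θ_d, which is how it is computed; a brute-force triple
loop is the test oracle. A topic is associated with a document when
θ_d(t) ≥ 0.01 (at least 1% of the document's words), and cluster-topic
association is the fraction of the cluster's documents associated with the
topic.

## Consensus clustering

PAM (k-medoids) is the base learner: greedy BUILD seeding, then
steepest-descent SWAP to a local optimum, with two pragmatic additions:
when the medoid-set space is tiny (C(n,k) ≤ 300) the optimum is found by
direct enumeration, and otherwise a few seeded random-restart SWAP passes
guard against the (real, if rare) local optima of single-start PAM — the
canonical single-start algorithm was verified to stall in the same local
optimum as R's `cluster::pam` on small unstructured instances.

Consensus clustering runs PAM on `reps` random 80% subsamples per k
(SGA space: k ∈ 4–6, 10 repetitions; topic space: k ∈ 4–10, 20
repetitions); consensus(i,j) is the fraction of co-sampling runs in which i
and j co-clustered. The final partition is PAM at the same k on
1 − consensus (several extraction rules are in circulation — hierarchical
cuts are the other common one; PAM on the consensus-derived distance keeps
a single base learner throughout), and robustness is the mean consensus
over within-cluster pairs.

**Distances.** SGA vectors are binary → Jaccard. Topic allocations are
probability vectors → total-variation (L1) distance. Euclidean distance
was evaluated first and squandered information that was demonstrably
present: on the default synthetic benchmark the fitted theta was ~99.8%
linearly separable by subtype, yet Euclidean consensus ARI was 0.75–0.80
across model seeds, versus 0.91–0.99 for L1 and 0.83–0.98 for cosine. L1
is the natural metric between discrete distributions and is the default;
both alternatives remain available via `FeatureSpace(distance=...)`.

## Survival

Kaplan–Meier product-limit estimation and the G-group log-rank test are
implemented from first principles (they are the pipeline's quantitative
endpoint); ties use the standard hypergeometric variance with d_t > 1
allowed, the statistic is a quadratic form over the first G−1 groups using
a pseudo-inverse, and p comes from χ²(G−1). `lifelines` serves as an
independent cross-check in the tests, never as the implementation. The
stratified analysis runs per cancer type, twice: over all clusters present,
and after excluding clusters with fewer than `min_cluster_size` (default
25) samples *of that cancer type* — the per-analysis unit, not the global
cluster size. Cancer types left with fewer than two clusters or no events
are skipped with a notice.

## Synthetic data generator

The generator plants exactly the structure the method claims to exploit.
Defaults (one fixed configuration, used by the benchmark):

| parameter | default | rationale |
|---|---|---|
| pathways × genes | 5 × 20 | enough rotation that two same-subtype tumors rarely share a driver (P ≈ 0.05/pathway) |
| subtypes | 4, 2 pathways each | combinations {0,1},{2,3},{0,2},{1,3}: every perturbed pathway covered by exactly 2 subtypes; pathway 4 stays unperturbed as a negative control |
| tumors | 600 | ~150/subtype; driver-gene recurrence ≈ 15 |
| theme tokens/pathway | 40 | distinct vocabulary themes |
| background tokens | 300 | shared vocabulary noise |
| background mixture weight | 0.5 | half of a driver gene's text is theme-free |
| passenger genes / rate | 300 / 0.002 | ≈ 0.6 passengers/tumor; per-gene recurrence ≈ 1.2, far below threshold |
| hazards | 1/300…1/1200 per day | distinct subtype prognoses (HR up to 4) |
| censoring | 0.25 | realistic loss to follow-up |

Driver alterations are emitted half as functional mutations, half as ±2
CNVs with expression shifted 4 reference SD (chosen so the concordance
filter recovers planted events essentially surely — testability, not
biological realism). Non-functional mutation noise (~1/tumor) and ±1 CNV
noise exercise the filters' rejection paths. Tokens are synthetic
identifiers containing digits, so Porter stemming is a no-op by design and
the stemmer is tested separately on natural vocabulary. Synthetic "cancer
type" labels are assigned independently of subtype, so clusters mix cancer
types and the per-cancer-type survival stratification is exercised.

What the generator does **not** emulate: realistic mutation spectra, gene
lengths, correlated passenger structure, expression covariance, or
annotation-text idiosyncrasies (abbreviations, citations, inconsistent
nomenclature). Passing the benchmark therefore shows the pipeline's
machinery is correct and that the heterogeneity-defeating premise works
when themes exist; it does not certify performance on real cohorts.

### Benchmark scaling

The benchmark (`oncothemes.pipeline.benchmark_params`) runs the 600-tumor
cohort with two size-scaled parameters: `min_recurrence = 5` (the default
20 corresponds to ~0.8% of a 2,396-tumor cohort; 0.8% of 600 is 5) and a
single 60-iteration nHDP fit (the restart ladder is a robustness device
for large noisy corpora; the planted corpus does not need it). The
whole-pipeline determinism check runs a further-reduced cohort (100–200
tumors, 12–15 iterations) twice and compares every serialized output
byte-for-byte.

## Numerical and degenerate-input choices

* All probability vectors are normalized to within 1e-9 and asserted so.
* Ranking ties (vocabulary boundary, vector boundary, PAM candidate order)
  break deterministically (lexicographic / smallest index).
* Empty documents: retained in outputs, excluded from likelihood, uniform
  theta over allocated nodes.
* A non-finite ELBO aborts the fit with the iteration index in the error.
* `adjusted_rand_score` conventions are inherited from scikit-learn
  (single-cluster truth vs non-trivial partition → 0).
* Every stochastic component takes an explicit integer seed; identical
  seeds and inputs give byte-identical serialized outputs at every stage.

## Known limitations

* The nHDP is truncated and variational; it finds a local optimum, and
  topic identity across restarts is not aligned (only the selected fit is
  interpreted).
* The CNV concordance test assumes an approximately normal copy-neutral
  expression reference; heavy-tailed expression would inflate calls.
* `p(g|t)` pools over all documents, which favors globally frequent genes
  within popular topics; per-gene conditioning would change rankings.
* The log-rank test is unadjusted: no covariates and no multiplicity
  correction across cancer types. Cox regression is out of scope.
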