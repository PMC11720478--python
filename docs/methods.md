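# Methods

This note documents the models and procedures behind `freeassoc`, the
parameter choices that matter, and what the synthetic-data validation
does and does not show.

## Data model

A study is three linked tables. `responses` holds one row per produced
token with a 1-based `response_position` inside each (participant, cue)
block; if the input carries no position column, positions are assigned
in file order. `participants` and `cues` are deduplicated covariate
tables; a participant carrying two distinct values for the same
covariate aborts the import rather than resolving first-wins, because
silently corrupted covariates would invalidate every downstream group
comparison. Rows with empty responses are dropped at import (with a
logged count). Duplicate (participant, cue, response) rows are retained:
in a snowball design the same word can legitimately be retrieved
repeatedly at different levels.

Targets — the unit of analysis — are fixed once, from cues, responses,
or their union, in first-occurrence order. Fixing them early is a
deliberate architectural constraint: response-based embeddings tabulate
the *next* response level for every target, which only exists when
targets are cues. Normalization after target-setting is rejected for the
same reason (it would desynchronize the target vocabulary).

## Normalization

Rules apply in the fixed order **whitespace → punctuation → case**, so
modal-casing statistics are computed on already-cleaned strings. Options
follow the conventions of free-association preprocessing: case `lower` /
`upper` / `sentence` / `most_frequent` (each case-insensitive form group
mapped to its modal spelling, ties broken alphabetically — a
deterministic build requires a rule); punctuation `all` or `end`; the
`end` rule strips the complete trailing punctuation run, not a single
mark (an assumption, documented here because a single-mark reading is
also defensible). Word-internal hyphens and apostrophes are kept —
"problem-solving" and "don't" are legitimate responses — while all other
Unicode punctuation (category P) is removed. Normalization is idempotent
for every configuration, preserves the token count, and never increases
the number of unique forms; these are tested as properties.

No automatic spellchecking is offered (context-free correction of
isolated words is error-prone); instead a wordlist export/import round
trip supports a manual pass, with response frequency as a rough
misspelling indicator. Corrections are applied in a single pass — two
forms mapping to each other swap rather than chain.

## Target characterization

* **Frequency** counts response tokens exactly matching the target
  string. The default scope is *first-level tokens only*: a target's
  first-level frequency determines how many second-level responses are
  available to embed it, so it is the relevant reliability quantity.
  `scope="all"` counts across levels.
* **Norms** are attached by exact string join against a user-supplied
  lookup table (word + numeric columns); unmatched targets get NaN. No
  third-party norm tables are bundled; the published affective-ratings
  and word-frequency databases can be loaded as plain CSVs.
* **Correlations** relate a per-participant retrieval indicator
  (produced the target at least once; repeated retrievals collapse to 1)
  to participant covariates: phi for binary covariates, point-biserial
  (Pearson on the indicator) for numeric ones. phi is computed by the
  2×2 closed form (n11·n00 − n10·n01)/√(n1·n0·n·1n·0), which equals the
  Pearson correlation of the 0/1 vectors — tested as an oracle
  equivalence. Because low-frequency targets give unreliable
  correlations, reporting defaults to the 50 most frequent targets
  (ties at the cutoff included); constant covariates yield NaN with a
  warning rather than an error.

## Embedding

The count matrix tabulates, per target used as a cue, the distribution
of its responses. PPMI uses the natural logarithm (the base only
rescales the matrix uniformly and cosine similarity is scale-invariant);
no smoothing or shifting by default, with optional context-distribution
smoothing (exponent α on the column distribution) exposed but off. Rows
are embedded as U_kΣ_k, the convention that preserves row dot products
at full rank (and hence cosine structure, verified to 1e-8 in tests).
Default k = min(100, min(N, M) − 1). SVD signs are fixed by making the
largest-magnitude entry of each left singular vector positive, so
repeated runs are bit-identical.

External embeddings go through a provider interface whose contract is
determinism (same text → same vector within an instance). The bundled
`HashEmbeddingProvider` derives each vector from a SHA-256 digest of the
text; it carries no semantics and exists to exercise and test the
external path. A real HTTP provider can implement the same protocol;
none is shipped or tested here.

Projections: PCA (deterministic), classical Torgerson MDS on cosine
distances (deterministic; implemented directly because the SMACOF
variant in common libraries is stochastic and does not guarantee that
duplicate inputs map to duplicate outputs), and UMAP (stochastic;
seeded).

## Clustering and stability

Louvain modularity optimization runs on a dense weighted graph whose
edges are max(0, cosine similarity), without self-loops: negative
similarity carries no affinity. Louvain chooses the number of clusters
itself (requesting k is an error); granularity is steered by the
resolution parameter (default 1.0). k-means operates on the embedding
vectors, hierarchical clustering on cosine distance with complete
linkage. Cluster labels are canonicalized 1..K by descending size. No
"optimal K" selection is provided: semantic spaces are organized
hierarchically with defensible partitions at several granularities, so
the package treats a clustering as a data summary whose trustworthiness
is quantified by stability instead.

Stability: each of B bootstrap replicates (default 100) samples N
targets with replacement, reduces to the unique sampled set — duplicate
nodes would distort modularity — and re-clusters the subset. For every
co-sampled pair the same/different-cluster outcome is recorded; the
pairwise proportion is co-assignments over co-occurrences (NaN for
never co-sampled pairs, which are excluded from aggregation). The
cluster-level K×K matrix averages pairwise proportions over pairs drawn
from the *reference* (full-data) clusters, avoiding any
bootstrap-to-reference label-matching heuristic. The chance level for
two targets landing together under independent uniform assignment into
K clusters is Σp² = 1/K (16.7% for K = 6), provided analytically by
`chance_coassignment`.

## Group comparison

Cluster-level cross-tables count response tokens per (group, target
category); normalization is within-group (rows sum to 1; empty groups
yield NaN rows). Characteristic-level comparison aggregates a numeric
target characteristic over each group's tokens — each token contributes
its target's value once, making the summary frequency-weighted — with
tokens lacking the characteristic excluded and reported as `n_missing`.

Representational similarity analysis rebuilds a PPMI-SVD embedding per
group from that group's responses alone (same k and smoothing as the
pooled embedding unless overridden), computes cosine-similarity matrices
on the targets embeddable in both groups of a pair (the intersection
rule; the count is reported as `shared_target_count`), and correlates
them with Spearman's ρ (average ranks on ties), either on the strict
lower triangles or as the mean of row-wise correlations with
self-similarities removed. With several participant variables, levels of
each variable are compared within-variable and additionally as full
level combinations. At least 3 shared targets are required; fewer is an
error, since the correlation would be meaningless.

## Synthetic data generator

The generator emulates the structure of a two-level mini-snowball study:
one top-level cue, `n_first` = 5 first-level responses, `n_second` = 5
second-level responses per first-level cue (30 tokens per participant),
participant groups drawn uniformly over gender × education by default,
and 1,000 participants in the default configuration. Latent topics have
disjoint pseudo-word vocabularies (hyphen-joined topic prefix, so word
forms survive normalization); first-level responses are drawn from a
group-adjusted topic mixture (multiplicative effects on base weights,
renormalized — so a multiplier of 2 on one of two equal topics yields an
expected share of 2/3), Zipf-distributed within topic (exponent 1),
without replacement within a cue block (people rarely repeat a response
to the same cue). Second-level responses stay in the cue's topic with
probability 0.8 (`topic_fidelity`), otherwise fall back to the
participant's mixture — this is the signal that makes response-based
embeddings recover topics. An optional `typo_rate` swaps adjacent
characters to exercise the wordlist round trip. `ground_truth` returns
the word→topic map, analytic per-group topic proportions, and the sign
of every injected effect.

What the generator does **not** emulate: real lexical content, polysemy
and overlapping topic vocabularies, response-position effects,
participant-level heterogeneity beyond group membership, and
misspelling patterns richer than adjacent transposition. Passing the
end-to-end recovery test therefore shows the pipeline is correct and
sensitive under clean, well-separated structure; it does not bound
performance on noisy human data, where topic overlap and low-frequency
targets will lower both stability and recovery.

## Problem sizes and numerical choices

The test suite and the acceptance script run at deliberately modest
sizes chosen to exercise every code path with comfortable margins:
oracle checks on ≤ 8×8 count matrices (100 draws) and 1,000 random 2×2
tables; stability on a 36-point 3-blob embedding at B = 50; the
independence null on 40 cues × 200 vocabulary words; end-to-end recovery
at 200 participants × 3 topics; the working-example emulation at the
full 1,000 participants. Tolerances: 1e-12 for formula oracles (pure
floating-point error), 1e-8 for SVD cosine fidelity (accumulated
linear-algebra error), |ρ| < 0.1 for the Monte-Carlo null. Degenerate
inputs are handled explicitly: zero count totals are an error, zero
embedding vectors are dropped with a warning before cosine computations,
constant covariates yield NaN correlations, never co-sampled bootstrap
pairs are excluded from aggregation.

## Known limitations

* Louvain on the dense similarity graph scales as O(N²) edges; the
  intended regime is N up to a few thousand targets. A top-k
  sparsification would be the natural extension for larger N.
* The first-level/second-level distinction relies on a `level` response
  covariate when present (first = smallest value); data without it are
  counted across all rows.
* Group-specific RSA embeddings are less reliable than the pooled
  embedding (roughly half the tokens per group in a two-group design);
  reported ρ values between small groups should be read qualitatively.
* No inferential statistics are attached to correlations, cross-tables
  or RSA values; the package reports descriptive quantities only.
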