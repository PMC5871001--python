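# Methods

## The model

`semsuggest` learns one dense vector per vocabulary word from a plain-text
corpus and defines "alternative query" as "nearby vector". Two
architectures are implemented, both trained by stochastic gradient descent
on a log-likelihood objective:

- **CBOW** predicts the center word from the *mean* of the context-word
  vectors inside a symmetric window.
- **Skip-gram** predicts each window word from the center word's vector,
  one (center, target) pair at a time.

The output layer is a **hierarchical softmax**: the vocabulary is arranged
as a Huffman binary tree over word frequencies, and

    P(w | c) = prod_k sigmoid(s_k * <v_{n_k}, c>) ,

where n_k are the inner nodes on the root-to-w path, s_k = +1 where the
path turns toward the bit-0 child and −1 otherwise, and c is the context
vector. Since sigmoid(x) + sigmoid(−x) = 1, the probabilities sum to one
over the vocabulary by construction, and one evaluation costs exactly
len(code(w)) dot products — O(log₂|V|) for frequency-balanced trees. This
is what makes training on large corpora feasible without a flat |V|-way
softmax.

Assumptions worth stating: adjacency within a document is the only context
notion (no sentence splitting, no syntax); the model is static (one vector
per type, no senses); and suggestion quality is purely geometric — cosine
similarity with lexicographic tie-breaks, no type filtering of the
returned terms.

## Phrase mining

Multi-word concepts are promoted to single tokens before training. For an
ordered adjacent pair (wᵢ, wⱼ),

    score(wᵢ, wⱼ) = (count(wᵢwⱼ) − δ) / (count(wᵢ) · count(wⱼ)) ,

and pairs with score above a threshold are joined with an underscore in a
greedy, left-to-right, non-overlapping pass. δ (default 5) discounts pairs
of rare words: any pair seen at most δ times scores ≤ 0 and can never
become a phrase. The default threshold 9·10⁻⁸ is the operating point
obtained by maximizing phrase overlap against ontology term labels; the
`ontology_overlap` helper reproduces that calibration for any corpus and
OBO files. Multi-pass merging (`max_phrase_passes` > 1) lets joined tokens
pair again, yielding trigrams and longer; the default is a single pass
(bigrams only).

## Tokenization

Tokens are maximal runs of Unicode word characters, lowercased, with the
underscore excluded (it is the phrase delimiter). A configurable
identifier pattern — by default letters immediately followed by digits,
optionally interleaved, with dotted or hyphenated suffixes — is matched
first, so database identifiers such as `at1g01010` or `q9s7u2-2` are never
split even where a hyphen would otherwise break the token. Lowercasing is
applied throughout because query matching must be case-insensitive.

## Training parameters

| parameter | default | meaning / why |
| --- | --- | --- |
| `dim` | 200 | vector dimensionality; the production-scale setting |
| `window` | 5 | context words per side; conventional for this family |
| `epochs` | 5 | corpus passes; loss plateaus after the first on clean corpora |
| `initial_lr` → `min_lr` | 0.025 → 1e-4 | linear decay over all training tokens |
| `min_count` | 5 | vocabulary frequency floor (1 in the tests' small fixtures) |
| `subsample_threshold` | 0 (off) | optional frequent-word subsampling, keep-prob `min(1, sqrt(t/f) + t/f)` |

Word vectors initialize uniformly in [−0.5/dim, +0.5/dim]; inner-node
vectors start at zero, which makes the untrained model assign
P(w|c) = 0.5^len(code(w)) exactly. Training is single-threaded and
bitwise-reproducible for fixed seed, config and corpus; no concurrent mode
is offered. The window is fixed (no per-position window subsampling) —
a deliberate divergence from some reference implementations, chosen so the
set of training pairs is a deterministic function of the corpus. In CBOW
the context update uses the exact gradient of the mean (each context word
receives 1/|context| of the error), again so that analytic and numerical
gradients agree to tight tolerance.

## Huffman construction and determinism

Classic two-least-weights merging with a stable tie rule: equal-weight
nodes merge in insertion order (leaves are inserted in vocabulary order —
descending frequency, ties lexicographic), and bit 0 goes to the
lower-weight, then earlier-inserted, child. The tie rule has no effect on
optimality (weighted code length is exhaustively verified optimal for
small vocabularies in the tests) but makes codes identical across runs. A
one-word vocabulary degenerates to an empty code: the single word has
probability one and training gradients vanish.

## Serialization

Models persist as a binary associative list: magic `QSM1`, little-endian
uint32 version / |V| / dim, then per word a uint16 UTF-8 byte length, the
term bytes, and dim float32 values. Vectors are stored (and compared in
tests) as float32; inner-node vectors are training state and are not
persisted. Loading validates the header and every record boundary and
reports the byte offset of the first inconsistency.

## Suggestion semantics

A query is tokenized, phrase-merged against the model's own phrase
inventory (vocabulary entries containing the delimiter), and resolved to a
vector: the joined phrase token if the vocabulary has it, otherwise the
mean of the known token vectors; a query with no known token raises an
out-of-vocabulary error (the HTTP layer maps this to an empty suggestion
list, the least surprising contract for embedding in a frontend). Ranking
is an exact cosine scan in float64 over the whole vocabulary. Zero-norm
vectors are excluded (cosine undefined); the query's own tokens and joined
phrase are excluded by exact string match only — near-duplicates like
*salinity stress* for *salt stress* are legitimate suggestions.

## Ontology information-content similarity

With P(T) = count(T)/total from a term-frequency table,

    Sim_Resnik(T1, T2) = max over common subsumers Ts of −ln P(Ts)
    Sim_Lin(T1, T2)    = 2·Sim_Resnik(T1, T2) / (−ln P(T1) − ln P(T2))

where subsumers are is_a ancestors and every term subsumes itself — which
is precisely what makes a suggestion recorded as a direct synonym (both
strings resolving to the same term) score Lin = 1 whenever P(term) < 1.
Only is_a edges are traversed; part_of and other relations are ignored.

Counts are **flat** by default: the table records how often each term's
string occurs in a corpus, with no propagation up the DAG. Flat counting
can make a subsumer rarer than its descendants, pushing the raw Lin ratio
above 1; values are clamped to [0, 1] and such rows flagged, preserving
the 0–1 scale. Classic Resnik propagation (a term's count becomes the sum
over its subtree) is available via `TermFrequencyTable.propagated` /
`--propagate-counts`. Degenerate inputs are errors, not silent values: no
common subsumer, a zero count on the rarest common subsumer (its IC would
be infinite), or both terms at P = 1 (Lin denominator zero).

Suggestion matching against ontologies is case-insensitive and exact,
labels before synonyms, first ontology in the configured order winning;
phrase underscores map back to spaces. In the evaluation driver, pairs
whose two terms match in *different* ontologies are dropped rather than
scored, since information content is only comparable within one hierarchy.

## Synthetic data: what it emulates and what it does not

`generate_synonym_corpus` plants the distributional-synonymy signal: 10
groups of 3 interchangeable words (the study condition for the recovery
experiment), 2,000 documents of 8 tokens, each document drawn from one
group with a 40% target / 50% context / 10% shared-background token mix
and 5 dedicated context words per group. Half of the context draws come
from the pooled context vocabulary of all groups (`context_overlap = 0.5`).
That admixture mirrors the generic vocabulary real prose shares across
topics, and it is what makes the planted structure identifiable: with
fully disjoint context vocabularies a context word's co-occurrence profile
is indistinguishable from a synonym's (the two play exactly symmetric
roles in the generative process), and the top-1 neighbour of a synonym is
as often a context word as a fellow synonym even when the learned clusters
are perfect. The overlap smears context-word profiles across groups while
synonyms keep pure profiles, so nearest-neighbour recovery measures what
it is meant to measure. Setting `context_overlap = 0` restores the
symmetric regime and degrades recovery gracefully — useful for probing.

What the generator does *not* emulate: word order and syntax (tokens are
exchangeable within a document), Zipfian frequencies, morphology,
polysemy, and document-length variation. Passing the recovery test
therefore shows the trainer extracts co-occurrence structure correctly; it
does not certify suggestion quality on real abstracts, which is what the
ontology-based evaluation module is for.

`generate_phrase_corpus` plants recurring adjacent bigrams in filler drawn
from a 300-word background vocabulary sized so chance adjacent repetitions
stay at or below δ — planted pairs clear the score threshold by
construction, chance pairs cannot. `generate_toy_ontology` builds is_a
trees whose counts decay geometrically with depth and whose root count
equals the table total, so P(root) = 1, sibling similarities are equal by
symmetry, deeper common ancestors are strictly more informative, and the
Lin clamp is provably a no-op.

## Problem sizes and numerics

The test suite trains at |V| ≈ 100, dim 16–50, ≤ 2,000 documents; the
recovery experiment averages 5 seeds at the study conditions above
(dim 50, window 5, 5 epochs). Exhaustive Huffman verification enumerates
all merge sequences for |V| ≤ 6. Gradient checks use central differences
at ε = 1e-5 with a 1e-4 relative-error bound, run on float64 parameters.
The logistic function clips its argument at ±50 to avoid overflow; cosine
ranking is computed in float64 regardless of storage dtype, and test
comparisons against the brute-force scan require identical rankings with
scores equal to 1e-9 (BLAS accumulation order differs between a
matrix-vector product and per-row dots).

## Known limitations

- No negative sampling or GPU path; hierarchical softmax only, as the
  serving-oriented design intends.
- The exact-scan suggester is O(|V|·dim) per query; fine for the
  vocabulary sizes here, no approximate-nearest-neighbour index.
- The HTTP layer is a WSGI app served by the standard library's wsgiref
  server: stateless, GET-only, no authentication or rate limiting — a
  development/embedding server, not a hardened deployment.
- Ontology matching is exact-string only; no fuzzy matching, stemming or
  cross-ontology reconciliation.
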