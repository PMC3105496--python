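# Methods

## Pipeline model

The package treats a text corpus as a bag of sentences.  Each sentence may
mention named bioinformatics e-resources and descriptor terms; all
downstream structure (profiles, similarities, networks, trees) is derived
from sentence-level co-occurrence alone.  No document-level windows,
anaphora resolution or name disambiguation are attempted: two spellings of
one resource are two resources.

### Mention recognition

A mention is a maximal run of *name tokens* immediately preceding and
including a *head word*.  A name token is capitalised, an acronym, contains
a digit, or is hyphenated; a small stop-list ("The", "We", "In", ...)
keeps sentence-initial function words out of names.  Head words are single
lowercase tokens mapped to the four semantic classes (e.g. *algorithm*,
*method* → Algorithm; *software*, *tool* → Application; *record*,
*sequence* → Data; *database*, *repository* → Data resource).  A bare head
word with no preceding name token ("the algorithm") is not a mention.
This deliberately simple recogniser replaces a full lexico-syntactic
named-entity system; it is sound on the fixture corpora this package
generates and on conventionally named resources ("SigCalc algorithm"),
but will miss names whose interior tokens are ordinary lowercase words
("Apollo Genome Annotation curation tool" breaks at "curation").

Sentence splitting is rule-based — a [.!?] run followed by whitespace and
an upper-case/digit/parenthesis opener, with an abbreviation stop-list
(e.g., i.e., cf., Fig., et al., vs., ...).  It is deterministic and
dependency-free; it will over-split on unusual abbreviations not in the
list, which only fragments co-occurrence contexts (it cannot create false
mentions).

### Descriptor tagging

Dictionary matching is case-insensitive exact token-sequence matching,
longest match first, left to right, with no stemming.  Hits overlapping a
resource mention are dropped: a resource's own name is not evidence about
itself.  A consequence of longest-match-first: when the longest candidate
at a position overlaps a mention, shorter alternatives at the same
position are not retried.

## Profiles and weights

`counts[r][d]` is the number of sentences in which r and d both occur;
repeats within one sentence count once.  The per-sentence cap is a design
choice (co-occurrence is defined at sentence granularity, so a sentence is
one event); the alternative — counting token repeats — would make weights
sensitive to list-like sentences.  Resources are keyed by
(lowercased name, semantic class), so a "X database" and an "X algorithm"
are distinct.  Descriptor columns that never co-occur with any resource
are dropped; they carry no information and would inflate the kernel.

tf\*idf uses tf = relative co-occurrence frequency within a resource's
profile and idf = ln(N/n_d).  The natural-log base is arbitrary (any base
rescales all weights by a constant, leaving cosines unchanged).  N = n_d
gives weight exactly 0: a descriptor seen with every resource is
uninformative by construction.

## Similarity methods

**Lexical profiles.**  LP(t) is the *set* of contiguous word n-grams of
the lowercased term; hyphenated tokens are kept whole, the full token
sequence is included, and vectors are binary indicators.  A k-token term
with distinct tokens has k(k+1)/2 n-grams.  Under this convention,
"protein data bank" vs "chip-chip data" = 1/√18 ≈ 0.2357 and
"basic local alignment search tool" vs "pairwise alignment" =
1/√45 ≈ 0.1491.  The originally reported values for these two name pairs
(0.28 and 0.18) are not reproduced by any convention we enumerated (hyphen
split/kept, full term in/out, contiguous vs subsequence n-grams, binary vs
count vectors, length- or idf-weighted cosines, Jaccard/Dice/overlap,
acronym in/out, character n-grams); the original tokenizer is not
recoverable from its description, so this package fixes the convention
above and documents the divergence rather than fitting to the printed
numbers.

**Shared descriptors.**  Reported as a cosine (unit-normalised inner
product) for both weightings so that similarities live in [0,1] and
1 − Sim is a valid dissimilarity; an all-zero profile has similarity 0 to
everything, including itself.

**Descriptor smoothing.**  A is computed once over the full descriptor
vocabulary as the Gram matrix of unit-normalised binary n-gram vectors —
symmetric, unit-diagonal and positive semi-definite by construction
(checked to minimum eigenvalue ≥ −1e−9 in tests).  Entries below 1e−12
are stored as exact zeros for sparsity.  Sim₃ uses kernel normalisation
(division by the square root of the two self-similarities), which gives
Sim₃(x,x) = 1 and keeps values in [0,1] by Cauchy–Schwarz.  When A is
exactly the identity the batch computation dispatches to the
shared-descriptor code path, which is algebraically identical and keeps
the two methods bit-for-bit comparable; the pairwise function keeps the
full quadratic-form computation, and the equivalence is verified to 1e−12.
Whether a restricted or full-vocabulary A is used only matters under
kernel normalisation when the restriction is inconsistent between the two
profiles; the full vocabulary is used throughout.

## Networks

Edges are created for every strictly positive similarity.  Pruning removes
an edge when its weight is strictly below the global median edge weight,
or strictly below the median incident weight of *either* endpoint (the
stricter of the two readings of a per-node rule; an edge must clear each
endpoint's median).  Strict-below removal means ties at the median
survive, so an all-equal-weight network is stable under pruning.  All
medians are computed once on the pre-pruning network; pruning is not
iterated to a fixed point, so re-pruning a pruned network can remove more
edges (medians have moved).  Isolated nodes are dropped from the output.
GraphML round-trips all node/edge attributes; SIF (with the weight in the
interaction column) and the edge-list TSV are edge-centric interchange
formats for Cytoscape-style tools.

## Clustering

Distances are d = 1 − Sim.  Ward's minimum-variance agglomeration is
applied *directly* to that table via the Lance–Williams update — the
behaviour of R's `hclust(method = "ward.D")` on a raw dissimilarity — and
is implemented in the package rather than delegated to
`scipy.cluster.hierarchy.linkage`, whose `ward` method implements the
ward.D2 variant and presumes Euclidean input.  1 − cosine distances are
not Euclidean; they are used as-is, without squaring, and this is a
documented convention, not an oversight.  Merge ties are broken by the
lexicographically smallest pair of cluster indices, making the merge
order fully deterministic; the implementation is validated against an
independent run of R's `hclust(ward.D)` on a frozen random dissimilarity
table.  Ward's Lance–Williams coefficients admit no inversions, so merge
heights are monotone and the tree can be cut (`maxclust`) and leaf-ordered
with the standard scipy utilities.  Newick branch lengths are differences
of merge heights, so every root-to-leaf path length equals the root merge
height (ultrametric).

## Synthetic corpora

The generator emulates the statistical shape the method exploits:
communities of resources with community-specific descriptor vocabularies
(two-word terms sharing a community stem token, so within-community
descriptors are also lexically related), a pool of generic descriptors
attached to sentences independently of community (the "gene"/"method"
phenomenon that motivates tf\*idf), and a noise rate at which topical
descriptors are drawn from a foreign community.  Sentences are fixed
template strings ("The {Name} {head} computes {d1} and {d2} using {g}."),
so the extraction stage parses its own fixtures end to end.  Defaults
(2 communities × 4 resources, 8-word community vocabularies, 3 generics,
10 sentences per resource, noise 0.05) are small enough to run in seconds
yet large enough that profiles overlap within communities; community
recovery experiments use 20 seeds at noise 0.1, which the Ward 2-cut on
tf\*idf shared-descriptor similarity recovers essentially perfectly.

What the generator does *not* emulate: realistic corpus scale, Zipfian
descriptor frequencies, multi-resource sentences, misspellings, or
ambiguous resource names.  Passing tests therefore demonstrate the
correctness of the machinery and the qualitative phenomena (smoothing
links lexically related profiles; tf\*idf suppresses ubiquitous
descriptors), not extraction recall on real articles.

## Numerical choices

- All similarity values are clipped to [0, 1]; symmetry is enforced by
  averaging with the transpose before use.
- Invariant checks use a 1e−9 tolerance; the kernel-identity equivalence
  is asserted at 1e−12; kernel sparsity threshold is 1e−12.
- Weighted-matrix and similarity TSV exports write `repr(float)` so
  round-trips are lossless.
- Degenerate inputs: an empty corpus yields an empty profile matrix;
  clustering requires ≥ 2 resources; a whitespace-only term has no
  lexical profile (error).

## Command-line interface

`bioresnet` exposes the stages (`simulate`, `extract`, `profile`,
`similarity`, `network`, `cluster`) and a `run-all` pipeline driven by
flags or a flat key=value config file (flags win).  Exit codes: 0 success,
2 configuration error (missing input path), 3 structurally empty result.
`--identity-kernel` is a debug flag forcing A = I so smoothed and shared
outputs can be diffed file-for-file.
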