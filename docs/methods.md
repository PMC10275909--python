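# Methods

## Model

The package tests pathway enrichment not on the measured gene list
itself but on a genome-wide *functional relevance* score derived from
molecular concepts (knowledge-based gene sets of any provenance:
ontologies, pathways, interaction neighborhoods, domain families).

**Concept weights.**  For an unweighted target list *T* (CSEA) each
concept C_i is weighted by the Ochiai (cosine) set similarity
ω_i = |T∩C_i|/√(|T||C_i|).  Ochiai rather than Jaccard because a small
concept nested in a large one keeps a high score (√(a/b) vs a/b), which
matters when concept sources of very different granularity are merged.
For a weighted list (WCSEA) the list is ranked by weight (descending,
ties by gene id) and each concept is scored by a weighted
Kolmogorov–Smirnov (WKS) running sum: hits step up by
|w|^exponent/Σ_hits|w|^exponent, misses step down by 1/(N−N_hit); ES is
the signed extremum (first position on exact ties).  ω_i = max(0, NES_i)
with NES = ES/mean(same-sign ES_random); concepts depleted in the list
(negative NES) carry no signature weight.  Flooring, rather than taking
absolute values, was chosen because a depleted concept is evidence
*against* functional relatedness, not for it (configurable in principle
at the call site by pre-processing the weight table).

**Penalized cumulative score.**  For gene x with concepts i = 1..n
(restricted to ω_i > 0):

- penalization ε_i = Σ_j O_ij over x's concepts, including the self term
  O_ii = 1, so ε_i ≥ 1 and nothing divides by zero;
- effective weight EW_i = ω_i/ε_i, effective concept number
  ECN = Σ_i 1/ε_i ≤ n;
- uniConSig(x) = Σ_i EW_i / √ECN, min–max normalized to [0,1] over the
  concept universe.

The √ECN denominator compresses the effect of concept count so the score
behaves like a redundancy-adjusted average of the ω's: one concept of
weight ω gives exactly ω; n exact duplicates also give ω.

**Duplicate collapse.**  Before computing ε/EW/ECN, concepts with
identical gene sets are collapsed to a single representative (they
necessarily share one ω, since ω is a function of the gene set).  The
ε-penalization is designed so that duplicated concepts count once, and
collapse makes that property *exact*: with the literal per-gene sum,
appending a copy of concept c also adds O_jc to every other concept j's
ε, perturbing scores at third concepts.  The standalone
`penalization_factors` API reports the literal, uncollapsed factors for
diagnostic use.  Note that two concepts containing the same gene always
overlap at least in that gene, so for minimal 2-gene concepts the
"independent concepts" limit (ε→1) is only approached as concepts grow.

**Zero-weight concepts are excluded** from both ΣEW and ECN: a concept
carrying no enrichment signal should neither add evidence nor dilute the
effective concept count, and exclusion keeps the single-concept closed
form exact.

**Pathway enrichment.**  Pathways are WKS-tested on the uniConSig-sorted
genome (normalized scores as weights, exponent 1).  The enrichment
universe is the concept universe plus the input genes; genes without
concept evidence are padded into the zero-score tail — the method's
point is that functional relevance, not presence in the measured list,
drives rank.  p-values are one-sided empirical frequencies against
sign-matched permutation nulls with add-one smoothing (k+1)/(n+1);
q-values are Benjamini–Hochberg (Bonferroni available).  Up- and
down-regulated pathways are analyzed in separate runs; the down run
negates weights before ranking.

**Permutation null.**  Gene-subset permutation (uniform subsets of the
ranked genes, size-matched to the tested overlap).  Sample-label
permutation would require expression matrices, which this tool does not
consume.  The null for ES depends on the ranked weights and the subset
size only, so one null per size is shared across equally sized sets
("shared" mode, default); per-set nulls ("per_set") are seeded from a
content hash of the set so results do not depend on call order.

**Disambiguation.**  Among the top-K pathways in rank order, each weaker
pathway B is re-tested against every kept stronger pathway A whose
overlap triggers (≥ 3 shared genes or Ochiai ≥ 0.05): the remainder
B \ A is WKS-tested on the same ranked genome; B's batch of remainder
p-values is adjusted (Bonferroni by default, α = 0.01) and B is pruned
when any adjusted p ≥ α.  A remainder smaller than 5 testable genes is
degenerate (nested/near-identical pathway) and prunes B outright.
Removal is greedy and immediate; removed pathways trigger no further
tests.  Adjusting within each candidate's own batch (rather than one
global batch) keeps the procedure single-pass, order-stable and
idempotent.  The rule is one-directional: a weaker pathway can never
evict a stronger one.

**Association.**  Pathway–pathway functional association is the CSEA
machinery applied reflexively: entry (i, j) is pathway j's NES when
pathway i's genes serve as the target list.  The matrix is symmetrized
by the arithmetic mean (max available), and the diagonal is set to each
row's maximum purely for display.  NES, not p, is used so edge weights
preserve magnitude.  Exports: TSV matrix, TSV edge list, GraphML.

## Synthetic data generator

`generate_fixture` emulates the situation the method targets: a weighted
gene list from a differential-expression comparison, a concept
compendium, and a pathway collection with known ground truth.
Background weights are Normal(0, noise_sd = 1) — the scale of a
z-statistic under the null.  Planted pathways' genes receive a +effect
mean shift; defaults used in tests (effects 0.7–2.5 on ~20–40-gene
pathways) correspond to clearly but not overwhelmingly perturbed
pathways.  For each planted pathway with positive effect, 5 "signature"
concepts are drawn containing a random 50–90% core of the pathway plus
random padding, emulating the overlapping, partially redundant knowledge
sets a real compendium supplies about a perturbed process; remaining
concepts and all other pathways are uniform random gene sets.  With no
planted effect the fixture is an honest null — signature concepts are
deliberately not built for zero-effect pathways, since a concept base
cannot capture a signal that does not exist, and coupling concepts to an
unperturbed pathway would spuriously inflate its significance.

What the generator does *not* emulate: realistic concept-size and
overlap distributions of curated databases, correlated expression noise,
compositional effects, or the amplification bias of single-cell library
preparation.  Passing benchmarks here demonstrate the machinery's
correctness and its dropout-buffering mechanism, not performance on any
particular biological dataset.

**Dropout** is simulated by deleting exactly round(f·N) genes uniformly
at random from the weighted list — what a DE pipeline would emit when a
gene goes unmeasured — not by zeroing weights.  Rank variation is
original_rank − perturbed_rank (negative = lost significance; a pathway
absent from the perturbed table gets rank K_new + 1), with five
replicates per condition by default.  The plain-WKS baseline runs the
same pathway test directly on the raw weighted list, isolating the
contribution of the concept-signature layer.

## Defaults and numerical choices

| parameter | default | rationale |
|---|---|---|
| concept size filter | [5, 2500] | tiny concepts make Ochiai unstable; bounds explicit and overridable |
| WKS exponent | 1 | standard weighted-enrichment convention; 0 gives rank-only mode |
| n_perm | 1000 | p-resolution 1/1001 with add-one smoothing |
| concept min overlap (WCSEA) | 3 | below this a concept's ES is dominated by single-gene noise |
| pathway min overlap | 5 | untestable pathways are skipped and logged |
| disambiguation α / method | 0.01 / Bonferroni | conservative independence criterion |
| disambiguation top_k | 30 | pathways are interpreted by rank; the head of the table is what users read |
| dropout replicates | 5 | per simulated condition |

Seeds are mandatory everywhere; sub-streams for pipeline stages
(concept weighting, pathway nulls, disambiguation, dropout replicates)
are derived via `SeedSequence` from the user seed and a stage tag, so
adding a stage never perturbs another stage's stream.  Ties are always
broken lexicographically by identifier.  Degenerate inputs are handled
explicitly: all-equal weights warn and fall back to id-order ranking;
all-equal raw scores normalize to all-zero with a warning; an all-hit
gene set has ES 1 by convention; a tested set with no same-sign null
samples gets NES 0, p 1 with a warning.  Exact duplicate gene tokens in
a GMT line are deduplicated silently (debug-logged); duplicate concept
ids are a hard error.

Leave-one-out CSEA scoring (each target gene scored with itself removed
from the target) is available via `leave_one_out=True`, using the closed
form ochiai(T\{x}, C) = (|T∩C| − [x∈C])/√((|T|−1)|C|); the default keeps
target genes in their own scoring.

Problem sizes in the shipped tests and the acceptance script (500–1000
genes, 20–50 concepts, 10–30 pathways, 300–1000 permutations) are chosen
so each claim is exercised with comfortable statistical margin while the
whole suite stays fast enough to run routinely.

## Known limitations

- Identifier harmonization is the user's job; gene ids are opaque
  case-sensitive strings.
- The genome-wide score is only as good as the concept compendium;
  a thin compendium gives a degenerate zero-heavy ranking.
- The disambiguation rule is greedy and one-directional; a genuinely
  independent pathway can in principle be pruned if a spuriously
  stronger superset precedes it.
- Association matrices require one full CSEA run per pathway and scale
  accordingly.
- No expression-matrix functionality: DE statistics, cell clustering and
  technical-noise simulation of count data are upstream of this tool.
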