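# Methods

## Problem setting

A protein–protein interaction network for a species with no interaction
data is predicted by *interolog transfer*: if the homologs of two
proteins interact in a reference organism, the interaction is
hypothesised in the target species. Unigenes (non-redundant assembled
transcripts) anchor the target species: a reference protein "matches"
the target when at least one unigene is homologous to it.

## Homolog selection

Inputs are BLASTX tabular (outfmt 6) hits of unigenes against each
reference proteome, in aligner output order. For each unigene × organism
block, the *first* hit with E-value strictly below the threshold
(default 1e-10) is selected. The first-hit rule trusts the aligner's
best-first ordering rather than re-sorting; a warning is logged if bit
scores are not non-increasing within a block. Ties at identical E-values
are therefore resolved by file order. A unigene selects at most one
protein per organism; a protein may be selected by many unigenes, and
the inverse map carries those unigene sets through the pipeline.

## Sub-network construction

Reference interactomes use the STRING `protein.links` dialect (combined
score = interaction probability × 1000). Confidence filtering keeps
edges with combined score ≥ 900 ("highest confidence", 0.9); the
threshold is inclusive and configurable. A sub-network keeps exactly the
interactions whose both endpoints have mapped unigenes. Proteins with
mapped unigenes but no surviving interaction are dropped: the object of
study is a network, and the per-organism statistics count proteins
inside it.

## Ordered integration and the cumulative score

Sub-networks are integrated one per round, ordered by phylogenetic
closeness to the target species (rank 1 first), with sub-network size
(edge count) breaking rank ties — larger first. In each round the
integrated network is the *target*, the incoming sub-network the
*query*.

**Node matching.** Cross-organism orthology is an explicit input table;
it cannot be inferred from unigene sharing, because orthologous proteins
mapped to *different* unigenes still count as a (score-1) match. A query
node merges into a target node when any of the target's member proteins
is orthologous to the query protein. When several candidates compete,
pairs are consumed greedily by increasing summed homology E-value, ties
broken lexicographically by query then target id; unmatched query nodes
enter as new nodes. Merging happens on any ortholog match (score 2 *or*
1); a score-1 merge unions disjoint unigene sets, which is what lets the
integrated network associate more unigenes than proteins.

**Scoring.** Per round, each edge present in the target and/or query
receives an edge-match component (3 both / 2 target-only / 1 query-only)
plus one protein-match component per endpoint (2 orthologous with a
shared unigene / 1 orthologous with disjoint unigenes / 0 no ortholog
this round). A node's protein score contributes to every edge incident
to it that round. Edges first appearing in round *k* carry zero entries
for rounds < *k*; their ledger starts at first appearance, which is what
makes 1 the attainable minimum. After *R* rounds every final score lies
in [1, 7R] — [1, 42] for the canonical seven-organism design — and the
score distribution is reported over six equal-width bins.

**Round statistics.** n1 = query nodes merged, n2 = query node count,
m1 = query edges whose merged endpoints already formed a target edge,
m2 = query edge count; ratios are reported as percentages with two
decimals; final node/edge counts are non-decreasing across rounds.

## GO handling

The ontology is parsed from OBO 1.2 via `obonet` and reduced to its
`is_a` skeleton; obsolete terms are skipped and `part_of` is deliberately
ignored (branch membership follows the subsumption hierarchy;
configurable in principle by extending the edge filter). Term depth is
the shortest `is_a` path to the namespace root (GO "level" conventions
vary; longest-path is available via a flag). A branch is its root plus
all `is_a` descendants. The branch sub-network keeps PIN proteins with
at least one annotation inside the branch and the induced edges;
isolated branch proteins are retained as nodes, since membership is
defined by annotation and connectivity is reported separately through
the connected-component summary. Level summaries count each protein once
per level ancestor (a protein under two level-1 branches counts in
both); no enrichment test is performed — the summary describes
proportions, not significance against a background.

## Evolutionary age groups

Organisms are partitioned into ordered phylostrata G1 < … < Gk (G1 the
earliest-diverging outgroup). A protein is dated to the earliest group
with an ortholog present; an all-absent presence row is an error
(undatable). An interaction's origin is the latest of three components:
its own interolog presence dating and its two endpoint datings — the
interaction cannot predate its last-appearing part. Interolog presence
rows are taken from the input presence matrix rather than recomputed
from the interactomes, because the orthology source for organisms
outside the reference panel is in general different from STRING; when an
edge has no row, the intersection of its endpoint rows is used (an
interaction can only exist where both partners do). Pathway origin
distributions cover pathways with more than a configurable number of
member proteins (default 10) and report per-group counts and fractions
summing to one; pathways without dated interactions are excluded with a
warning. Branch lengths and divergence times are not modelled.

## Neighbour annotation

The guilt-by-association step assigns to each unclassified protein every
term whose support among annotated direct neighbours reaches
`max(min_support, ceil(vote_fraction × annotated_neighbours))`, with
defaults `min_support = 2`, `vote_fraction = 0.5`. The procedure is a
single pass by default — decisions use only the prior annotation state —
with an optional iterative mode that feeds new annotations back until a
fixed point. Votes are counted on terms exactly as annotated; an
optional flag expands each vote with the ancestor closure. These
defaults are an explicit design choice: a support requirement below
unanimity but above single-witness keeps precision while leaving weakly
connected proteins unannotated, which is the observed behaviour of this
family of methods (a substantial minority of unclassified proteins
remains so). Unigenes inherit the union of their proteins' terms; a
unigene counts as previously classified if any of its proteins was
annotated beforehand. Coverage is reported as newly-annotated ÷
previously-unclassified and remaining-unclassified ÷ total, per entity
class, with one-decimal percentages; depth histograms count each entity
once per distinct depth of its assigned terms.

## Synthetic data: what it emulates and what it does not

The generator produces all pipeline inputs from one seed,
byte-deterministically:

- **Interactomes** share a common backbone (60% of each organism's
  edges) plus organism-specific edges, both sampled with heavy-tailed
  endpoint weights (rank^-0.7) so hub proteins dominate, as in curated
  interactomes. Expected edge count per organism is
  `edge_density × C(n, 2)`; isolated proteins are tied in with one extra
  edge so every protein appears in its links file. 80% of combined
  scores are ≥ 900, the rest 400–899, so the confidence filter removes a
  real minority.
- **Ortholog chains**: consecutive organisms share a random
  `ortholog_overlap` fraction of protein indices; chains that span all
  organisms, break midway, or never form produce protein-match scores of
  2, 1 (via unigene splits) and 0 during integration.
- **Homology hits** per protein index follow one of four modes — one
  unigene across all organisms (60%), two unigenes split across a cut in
  the chain (15%), two unigenes on the same protein (10%), or hits that
  all fail the E-value cutoff (15%) — with decoy secondary hits at worse
  E-values, and bit scores non-increasing within each unigene–organism
  block.
- **GO DAG**: a biological-process root with six canonical level-1
  children including the immune branch, plus randomly attached deeper
  terms (20% with two parents, giving diamonds) and one obsolete stanza;
  the immune branch always carries at least eight annotated protein
  indices.
- **Age groups**: organisms in generation order are the closest
  relatives first (integration ranks 1…n) and are binned into groups
  Gk…G1 nearest-to-outgroup, so presence runs along ortholog chains give
  non-trivial earliest-group datings.

Default scale is 7 organisms × 200 proteins × 400 unigenes at edge
density 0.05 — small enough that a full run takes about a second, large
enough that every score component, bin and stage is populated. The
generator does **not** emulate sequence content, alignment biology
(E-values are sampled, not computed), STRING's channel sub-scores,
assembly artefacts, or annotation noise; passing tests therefore
demonstrate the correctness and determinism of the pipeline's logic on
structurally realistic inputs, not the biological accuracy of interolog
transfer on real data.

## Numerical and degenerate-input choices

- Score components are small integers; no floating-point tolerances are
  involved anywhere in scoring.
- Edges are stored canonically (sorted endpoint pair); all iteration is
  over sorted containers, making every stage deterministic.
- Ratios with zero denominators (e.g. m1/m2 for an edgeless query) are
  reported blank rather than zero.
- Merge tie-breaks: smallest summed homology E-value, then
  lexicographic query id, then target id.
- An organism offered twice for integration, a homology map for the
  wrong organism, conflicting id-map rows, cyclic ontologies, and
  out-of-range configuration values all raise typed errors early.

## Known limitations

- The ortholog table is an input; the package does not compute
  reciprocal best hits. Garbage orthology gives garbage merges.
- Node matching is greedy one-to-one per round, not an optimal
  assignment; with realistic (sparse, near-functional) ortholog tables
  the difference is immaterial, but pathological many-to-many tables
  could merge suboptimally.
- Integration order matters by design (target vs query asymmetry, 2 vs
  1); only the rank/size rule is automated, and equal-rank/equal-size
  ties fall back to organism id.
- GO depth uses shortest paths by default; analyses keyed to longest-path
  "levels" should pass `mode="longest"`.
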