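# Methods

## Scoring model

A *gene order* is a circular sequence of occurrences over a closed 38-token
alphabet: 13 protein-coding genes, 2 rRNAs, 22 tRNAs and the control region
(CR), which is treated as a single gene. The light-strand replication
origin (O_L) and pseudogenes are excluded at parse time because their
annotations are too inconsistent across records to compare.

Scoring compares each occurrence's two nearest flanking neighbours with the
flanks of the same gene in a reference arrangement where every label is
unique. Two modes exist:

- `ordered` (default): left flank vs reference left, right vs reference
  right. The reading direction of a mitogenome record is fixed by
  convention, so orientation of the comparison is meaningful.
- `unordered`: the observed flank pair is matched against the reference
  pair as an unordered multiset; the score is the size of the multiset
  difference. Unordered RS ≤ ordered RS always.

The two worked anchors — genome RS = 2 for a single tandem duplication and
RS = 10 for the typical neobatrachian arrangement against the vertebrate
reference — are identical under both modes, so the mode is exposed as a
flag and recorded in every report header rather than hidden.

Conventions that the model fixes:

- Duplicated genes: every occurrence is scored independently against the
  single reference context of its label; neighbour *labels* are compared,
  never copy identities. A tandem pair therefore scores 1 + 1 (one changed
  flank each).
- Lost genes score nothing themselves (no occurrence); their absence is
  captured by the changed flanks of the surviving ex-neighbours.
- RF denominator: 2 × occurrence count, accumulated over the group, so
  duplicated genes enlarge the maximum attainable RS of their label. RF is
  computed in full precision and rendered to 2 decimals; genes without
  occurrences in a group have *undefined* RF (reported missing, never 0).
- Conserved segments are maximal circular runs (length ≥ 2) of
  reference-adjacent genes with RF exactly 0; undefined RF breaks a run.

## Canonicalization and census

Circular orders are compared after rotation to a deterministic start:
trnF (the conventional vertebrate record start), falling back through
rrnS, cox1, nad5 when absent, and to the lexicographically minimal rotation
when all four are missing. A duplicated start gene is resolved to the
occurrence giving the lexicographically smallest tuple. Strand is parsed
and preserved but excluded from both scoring and pattern identity by
default; the token-level strand-sensitive view exists behind a flag.

Census classes: *major* ≥ 3 members, *double* = 2, *single* = 1
(double ∪ single = *rare*). Major patterns are ranked by descending count,
ties broken by first appearance in the input. Local censuses either project
to a label subset (the 13 PCGs) or extract the span strictly between two
anchor genes. Built-in regions: Region 1 = (nad4, rrnS), Region 2 =
(nad1, cox1), Region 3 = (nad4, CR) filtered to {nad5, nad6, cob}. A genome
whose anchor is missing or duplicated is excluded from that region's census
with a warning — a genome with a duplicated CR, for example, still enters
the Region 1 census but not Region 3.

## Phylogenetic tests

The clustering question is operationalized as per-clade enrichment: for
every internal node whose clade holds between 2 and N−1 tips, the count of
labeled tips is tested against the upper tail of the hypergeometric
distribution, and the minimum Bonferroni-adjusted p over the tested nodes
is the summary. This is the simplest construction consistent with reporting
a single "hypergeometric test" p-value for tree-wide clustering; because
the construction is a design choice, every report records it. Combinatorics
go through `scipy.stats.hypergeom` (log-space internally); an exhaustive
enumeration oracle checks the tail for all populations N ≤ 12 in the test
suite.

The sampling-density test is a single upper-tail hypergeometric draw:
population = all sampled species, successes = species whose family
contributed ≤ 2 species, draws = rare-arrangement species.

Pattern ages: the MRCA age of the species sharing a pattern is the *latest*
possible origin of that pattern, valid under the assumption that identical
arrangements are homologous rather than convergent. Ages come from
ultrametric branch lengths (`dendropy` node ages, ultrametricity tolerance
1e-4) or from a sidecar node-label→Ma table; tree inference and divergence
dating are out of scope — trees and dates are inputs.

## Simulator

`simulate_tree_dataset` evolves a root arrangement along a tree: per branch
the event count is Poisson(total rate × branch length), events are applied
sequentially, and descendants inherit ancestral orders (no back-mutation
model), which produces phylogenetically clustered rearrangement by
construction. Event types and defaults (events per branch-length unit, on
coalescent trees of height ≈ 1):

| event | rate | note |
|---|---|---|
| tandem_duplication | 0.25 | block duplicated in place, no loss |
| tdrl | 0.35 | tandem duplication–random loss: one copy of each duplicated gene deleted uniformly at random; the identity outcome is allowed |
| transposition | 0.20 | block excised, reinserted at a drawn position |
| inversion | 0.10 | block reversed in place (labels only under the strand-agnostic default) |
| loss | 0.10 | single genes only; rejected and resampled if the order would drop below 2 genes |

TDRL gets the largest share as the mechanism generally accepted to drive
mitogenome rearrangement; the absolute scale is a placeholder — real
per-lineage rates are unknown — and the rate vector is a parameter, not a
claim.

Block lengths are geometric with mean 2 genes, truncated at 6, matching the
small tRNA-cluster rearrangements that dominate observed patterns. Event
placement follows *hotspot weights*, a probability mass over reference
genes; the default puts 45 % on the Region 1 interior (H…F: the nad5–CR
segment), 45 % on the Region 2 interior (I…Y: IQM–WANCY) and spreads 10 %
uniformly elsewhere. When the weight vector contains zero-weight genes,
spans truncate at the first cold gene and transposition destinations are
drawn from the warm genes, so fully concentrated mass confines events to
the hotspot: all RF > 0 genes then lie within the *closed* anchor-to-anchor
span (the anchors themselves can gain score through their perturbed flanks,
which is why the closed span, not the open interior, is the right support
statement).

Every simulation returns an event log (branch, type, affected span, replay
parameters, resulting order); replaying the log from the root reproduces
each tip order exactly, and identical seeds give identical datasets.

What the simulator emulates: clustered rearrangement on a tree,
hotspot-concentrated events, the five event types, duplicated and lost
genes. What it does not: sequence evolution, annotation error, duplicated
control regions with concerted evolution, mechanistic differences between
TDRL variants (TDNL/DMNR/DRRL), or realistic event-rate ratios. Passing
parameter-recovery tests therefore shows the *statistics* behave correctly
on data with the assumed structure, not that real amphibian data meet the
assumptions.

## Problem sizes and numerical choices

Stochastic test properties use fixed seeds with deliberate replication:
rate-monotonicity of mean tip RS averages 10 replicate 60-tip coalescent
trees per rate level (tip scores within one tree are strongly correlated
through shared deep branches, so replicate trees, not more tips, carry the
information); the clustering power check paints one ~27-tip clade of a
128-tip tree and compares against 50 label shuffles. The exhaustive scoring
oracle covers every circular order of length ≤ 7 over a 5-letter alphabet
in both modes.

Known limitations: the package compares gene orders only (no breakpoint or
inversion distances, no event-history reconstruction between two orders);
the leucine/serine tRNA labels follow the positional convention (L1 after
rrnL = Leu(UUR), L2 next to nad5 = Leu(CUN), S1 after cox1 = Ser(UCN), S2
after trnH = Ser(AGY)), which inverts the anticodon-tag convention of some
annotation pipelines — the synonym table accepts anticodon-qualified
spellings of both; and the undefined token "V1" seen in some published
arrangement strings is read as trnV with a warning rather than guessed at.
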