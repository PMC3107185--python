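# Methods

`lcbphylo` implements a whole-genome homology-to-phylogeny workflow for
closely related bacterial genomes, together with a genome-evolution
simulator that provides exact ground truth for validating every stage.
This note records the models, the numerical choices, and what the bundled
validation studies do and do not show.

## The analysis model

The workflow treats unannotated genome sequences as the raw material for
*primary homology*: hypotheses that particular stretches of different
genomes descend from the same ancestral sequence.  Because bacterial
genomes rearrange, a single global alignment is meaningless; instead the
genomes are decomposed into **locally collinear blocks (LCBs)** —
contiguous segments shared by two or more genomes within which no
rearrangement has occurred.  Blocks present in *every* taxon are aligned,
concatenated into one partitioned super-matrix, and analysed
phylogenetically; the tree then serves as the framework for interrogating
gene and genome history (annotation projection, multi-copy gene tracking).

### LCB detection

Anchors are exact k-mers (default k = 15, canonical strand form) that occur
exactly once in each genome that carries them; per-genome uniqueness
excludes repeat families, so anchors behave like unique-match seeds.
Anchors sharing a taxon set and relative orientation pattern are chained
while consecutive anchors keep the same order and orientation in every
shared genome with gaps of at most `max_gap` (default 5,000 bp).  Chains
claim genome intervals greedily — larger taxon sets first, then more
anchored bp — and lower-priority chains are re-walked around claimed
intervals, so a subset chain nested inside an all-taxa block dissolves
rather than double-claiming sequence.  Discarding chains with fewer than
`min_chain_bp` (60) anchored bp suppresses chance k-mer collisions.

Chain extents become block segments.  Boundaries are extended outward by at
most `boundary_ext` bp (default 50), never past the midpoint to a
neighbouring chain.  The cap is deliberately at anchor scale: in validation
runs, longer unanchored extensions mainly pulled in sequence from beyond
rearrangement breakpoints, asserting homology the anchors never supported —
the affected leading columns of such blocks paired non-homologous bases for
most of their length, and the shared-breakpoint states they introduced
mimicked phylogenetic signal.  Because segments of distinct blocks never
overlap within a genome and each block holds at most one segment per taxon,
the induced mapping between any two genomes is a partial bijection (checked
on every run).

The detector also records, in each block, the positions of periodic
internal anchors (every ~4 kb).  These are exactly homologous cut points
that the aligner may use (below).

*Sensitivity.*  Exact 15-mer anchors conserved across *all* taxa become
vanishingly rare once root-to-tip divergence exceeds roughly 0.05–0.08
substitutions/site on deep trees; beyond that the detector still produces
subset blocks but all-taxa coverage collapses.  This is the key fidelity
gap relative to progressive genome aligners such as Mauve, which anchor
pairwise along a guide tree and therefore tolerate far higher divergence.
All simulation studies are run at 0.05 substitutions/site root-to-tip.

### Alignment and concatenation

Each block is aligned by progressive profile–profile Needleman-Wunsch
following a UPGMA guide tree built from 1 − shared-8-mer-fraction
distances.  Scores: match +2, mismatch −1, affine gaps −4 to open and −1 to
extend; `N` is scored as a mismatch against everything.  Dynamic-programming
ties prefer diagonal, then vertical, then horizontal moves, making the
output deterministic.  Two standard profile refinements are used: (i) gap
penalties are scaled by the non-gap fraction of the column being gapped, so
extending an existing mostly-gap column is nearly free (the position-specific
penalty idea of mainstream profile aligners); (ii) when the detector
supplied internal anchor cut points, the block is aligned window-by-window
between consecutive cut points.  Windowing bounds how far the true path can
drift from the DP diagonal, so a narrow band (default 64, plus the profile
length difference) is exact in practice; a band at least as long as both
sequences makes the DP exhaustive, which is how the aligner is validated
against a naive full dynamic program.

A further post-pass separates stacked independent insertions: minority-base
gap runs whose inserted sequences cluster into dissimilar groups are
rewritten with one column block per group, since such stacked columns
would otherwise manufacture shared-gap characters grouping the inserting
taxa under fifth-state scoring.  An optional genome-scale guide tree
(``build_guide_tree``) can replace the per-window guides; it is off by
default because a single guide that mis-resolves a short branch stamps
that resolution into every ambiguous indel genome-wide.

Aligned blocks are concatenated in block-id order into a taxa × columns
matrix with a partition table; taxa absent from a block are padded with
gaps across its partition.  Column jackknife (without replacement) and
bootstrap (with replacement) subsampling are seeded and deterministic.

### Tree inference

Parsimony uses Fitch counting with two gap treatments.  Under
`FIFTH_STATE`, a gap is a character state of its own (a shared deletion can
group taxa); `N` remains fully ambiguous.  Under `MISSING`, both `-` and
`N` are fully ambiguous, so gaps carry no grouping information and the
`MISSING` length never exceeds the `FIFTH_STATE` length.  States are bit
masks, so set operations vectorise over alignment columns; columns are
compressed to unique site patterns, and parsimony-uninformative patterns
(whose length, number-of-states − 1, is the same on every topology) are
scored once rather than per candidate tree.

Tree search is a deterministic, seeded simplification of a parsimony
ratchet: random-addition Wagner starts; steepest hill climbing over the
full SPR neighbourhood (which contains every NNI); then a reweighting
ratchet (double the weight of a random 25% of patterns, re-search, restore,
re-search).  Every distinct topology encountered at the best score is
retained (capped at 1,000), so tied resolutions are reported rather than
hidden.  The searcher is validated against exhaustive enumeration of all
topologies at 4 and 6 taxa.

Distance trees use standard neighbor joining on model-corrected distances.
JC69: d = −(3/4) ln(1 − (4/3) p) with p the mismatch proportion over sites
where both rows are ungapped and unambiguous.  TN93 uses its closed form
with the two transition classes and empirical base frequencies estimated
per pair; HKY distances are served by the same formula (HKY is TN93's
equal-transition-class special case).  Saturated pairs (log arguments ≤ 0)
raise an error naming the pair.  NJ on an exactly additive matrix provably
returns the generating tree with exact branch lengths, which is asserted in
the tests.

### Support and indel accounting

Rather than bootstrapping the multi-megabase matrix, support is measured
two ways: (i) **concordance counts** — each internal edge of the genome
tree is annotated with the number of individual-block trees containing the
same bipartition (trees with missing leaves are pruned to the common leaf
set first); (ii) **column jackknife** — random column subsets of fixed
sizes are re-analysed and compared topologically.  Robinson-Foulds
distances and unique-topology counts are computed from canonicalised
bipartition sets.

The **indel-step decomposition** asks how much of a fifth-state tree length
is gap-derived.  Fitch sets are computed bottom-up; a top-down pass assigns
each internal node its parent's state when available, otherwise the
smallest member of its state set in A < C < G < T < '-' order (a
deterministic refinement that realises the Fitch length).  A step is an
edge whose endpoints receive different states; it is an indel step when
either endpoint is the gap state, and internal when the child endpoint is
an internal node.  Per-column counting deliberately treats a k-column gap
as k events; merging runs of gap columns into single events is a coherent
alternative definition that is *not* implemented, and the per-column choice
is the one consistent with fifth-state tree lengths.

### Annotation projection and copy tracking

Features are mapped through each taxon's gapped row into alignment columns
(strand-aware); residual non-gap columns are labelled non-coding, so gene
plus non-coding columns always account for exactly the row's non-gap
columns.  A gene overlapping a block boundary counts once in gene tallies
but contributes only its overlapping base pairs to composition accounting.

For a multi-copy family (the rRNA case), every copy is extracted
strand-corrected, assigned to the block covering at least half of its span
(block non-overlap makes this unique), and laid out in a block × taxon
grid.  Positional orthology holds iff some single block carries a copy for
every taxon.  All copies are aligned together and a fifth-state parsimony
tree built; each species' copies are classified MONOPHYLETIC,
PARAPHYLETIC (their smallest enclosing clade adds exactly one foreign
clade) or POLYPHYLETIC (anything deeper), on the tree rooted above the
outgroup's copies when an outgroup is named.  The **concerted-evolution
index** is the fraction of multi-copy species classified monophyletic.

## The simulator

A random root genome is laid out with genes (normal lengths around
`mean_gene_length`), intergenic spacers (exponential, tuned to
`gene_density`), and `n_rrna_copies` copies of an rRNA template; copies
receive root-era paralog divergence (`rrna_paralog_divergence`, pairwise).
The genome evolves down a Yule tree rescaled to root-to-tip depth 1.0, so
all rates read on the root-to-tip scale.  Per branch, in order:
Jukes-Cantor substitutions (exact transition probabilities; rRNA sites at
`rrna_rate_scale` = 0.1 of the background rate, emulating rRNA
conservation); within-genome gene conversion of the rRNA family (an event
overwrites one copy's span with another copy's content, preserving the
recipient's orientation); indels (Poisson counts, geometric lengths,
insertions of uniform random bases); inversions (reverse-complement in
place); translocations (excise, reinsert uniformly).  Horizontal transfer
(`hgt_rate`, default 0) is modelled as acquisition of foreign de-novo
sequence.

Every site carries its root coordinate, orientation, and feature id
through all of this, so each leaf genome comes with an exact site-level
homology map (the truth map) and a reconstructed feature table.  Identical
configurations reproduce byte-identical FASTA/GFF3/TSV output.

Detection quality is scored against the truth map at single-base
resolution: an aligned column asserts homology between the genome positions
it pairs; precision is the fraction of asserted pairs whose sites share a
root coordinate, and recall the fraction of root coordinates shared by a
genome pair that some column recovers, micro-averaged over pairs.

**What the simulator does not model:** among-site rate heterogeneity,
base-composition bias and codon structure, selection, recombination or
incomplete lineage sorting, plasmids, and realistic repeat families beyond
the rRNA operons.  Clean Jukes-Cantor data makes per-block trees more
accurate than real per-block trees at the same divergence, which is why
the block-discordance study (below) uses a high breakpoint density to keep
per-block information content low.  Passing these studies shows the
pipeline is internally sound and statistically consistent under its own
model; it does not show robustness to model violations in real data.

## Validation studies (bundled conditions)

Three seeded studies in `lcbphylo.studies` fix the conditions used by the
test suite; sizes were chosen so a full study runs in minutes on one CPU.

1. **Parameter recovery** — 12 taxa, 300 kb genomes, root-to-tip divergence
   0.05, indels at 0.004/site, inversions and translocations at 2.5 and
   1.5 events per unit branch with 0.5–4 kb segments, which fragments the
   genomes into tens of all-taxa blocks so each block alone carries weak
   signal.  The rRNA family is reduced to 2 unconverted copies: at this
   genome size a full-size converted family is ~5% of the sequence (10×
   its real-genome share), and its homogenised paralog content measurably
   drags the concatenated tree toward wrong topologies — concerted
   evolution is exercised in study 2 instead.  Measured per seed:
   Robinson-Foulds distance of the concatenated fifth-state parsimony
   tree to the true tree; the fraction of all per-block
   equally-most-parsimonious trees that differ from the genome tree; and
   whether a 20,000-column jackknife recovers the genome topology (it
   counts as recovered when the topology is among the subsample's tied
   most-parsimonious trees, as a program reporting all MPTs would show).
2. **Concerted-evolution contrast** — 6 taxa, 50 kb, a 3-copy rRNA family,
   two arms from each regime's stationary state.  Conversion arm: root
   copies identical, 100 conversion events/copy/unit branch — well above
   the inverse of the shortest Yule internodes, because within-family
   polymorphism that survives an internode sorts into the daughter
   species like allelic incomplete lineage sorting and scatters copies
   across species (at 3–10 events/copy the index plateaus near 0.7 for
   exactly this reason).  Null arm: no conversion, 20% root-era paralog
   divergence.  The rRNA clock runs at half the background rate in this
   study so every species carries diagnostic copy variants.  The mean
   concerted-evolution index over seeds is compared against 0.9 (high
   conversion: copies cluster by species) and 0.3 (no conversion: copies
   cluster by paralog).
3. **Detector contract** — 8 taxa, 100 kb, low rearrangement (about one
   event per branch).  Block homology must form a partial bijection on
   every run, and base-level precision and recall against the truth map
   must both reach 0.9.

The parameter-recovery study also documents a measured limit: on a few
per cent of Yule trees, one internal branch is so short that the handful
of true substitutions it leaves is outweighed by gap-pattern homoplasy —
repeat-context indels from independent lineages whose placement is
positionally unidentifiable — and the fifth-state parsimony tree then
misses exactly that branch while recovering every other.  A perfect-
homology control (substitutions only, genomes fed to parsimony directly)
recovers every tree including 0.0007-length branches, placing the effect
in block detection plus alignment, not in the tree machinery.

## Known limitations

- The exact-k-mer anchor detector restricts usable divergence (see above);
  real Mauve-scale divergence is out of reach for all-taxa blocks.
- Paraphyly detection is limited to the single-nested-clade case; deeper
  grades report POLYPHYLETIC.
- Parsimony branch lengths are not computed; fifth-state lengths treat
  multi-column gaps as independent events.
- Blocks are linear; a block spanning a circular origin is split.
- The MP searcher's tree cap (1,000) can truncate enormous tie sets on
  information-poor matrices.
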