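# Methods

## The detection model

The unit of analysis is a CNE alignment: gapped sequences for up to 43
species on a shared column frame, anchored to an interval on a reference
genome (all coordinates 0-based half-open; GFF input is shifted at the
I/O boundary).  Detection always compares a species against a
*reconstructed ancestor*, by default the tetrapod root.  Windows are laid
over the ancestor's **ungapped** positions — columns where the ancestor
carries a gap hold no ancestral base, so including them would dilute
window thresholds with alignment artefacts of other species — and mapped
back to columns for scoring.

The identity kernel counts absolute matches per window, never fractions,
because the published thresholds are absolute (18/20, 14/20, 30/50).  A
column matches only when both sequences carry the same A/C/G/T base; a
gap or N on either side is comparable but never a match, so a fully
deleted window scores 0/20.  A species is called degenerated in an
element as soon as one window fires under either criterion; all firing
windows are recorded as evidence.  "Absent" in the long-window criterion
means 100% gap/N across the focal window (`absent_fraction`, default
1.0, exposes a laxer reading).  The ≥ 29 limbed-support count is
evaluated per window.  Species with no record in an element count as not
degenerated for lineage calls, so assembly gaps cannot inflate
convergence; species whose record is entirely gap are present and can
fire the absence criterion — that is precisely the fully-deleted-element
case the criterion exists for.

Two open choices are parameters: the comparison node for the focal
species (default: tetrapod ancestor, the node the limbed-conservation
clause names; each lineage ancestor is available), and the per-window
versus per-element reading of the limbed-support clause (per-window,
following the sentence structure of the criteria).

## Ancestral reconstruction

Internal-node sequences come from Fitch parsimony with the gap as a
fifth character state and N as full ambiguity, run per column with a
deterministic refinement: the root takes the first state of its
candidate set in the fixed order A < C < G < T < '-', and a child keeps
its parent's state whenever possible.  A probabilistic,
alignment-coupled reconstruction would be heavier without changing what
the thresholds measure; externally produced ancestor sequences can be
supplied per element to bypass this stage.  Species that are absent or
fully gap/N in an element are pruned from its reconstruction; elements
with fewer than two informative species are flagged unreconstructable
and excluded downstream.  Parsimony optimality is property-tested
against exhaustive enumeration of all internal labellings on small
trees.

## Synthetic study conditions

The generator emulates the comparative design end to end and is the sole
source of inputs for tests and the acceptance script.  Its defaults are
the study conditions:

- **Phylogeny.** 31 limbed species plus 12 limbless in four monophyletic
  lineages — 4 caecilians (limb loss 192 Mya), 6 snakes (170 Mya) and
  two single-species lizard lineages (40 and 35 Mya) — on an ultrametric
  tree of depth 352 Myr with labelled root and lineage-ancestor nodes.
  Topology within clades is pectinate; node ages are fixed constants, so
  the tree is byte-stable across runs.
- **Rates.** Every species carries a neutral rate of 0.002
  substitutions/site/Myr, a typical vertebrate neutral rate; per-lineage
  rate estimates are not published for the source design, and a constant
  keeps the neutral contrast interpretable.  Branch lengths in expected
  substitutions are Myr × mean leaf rate below the branch.
- **CNE evolution.** Sequences evolve site-independently under a
  normalised GTR chain (default Jukes–Cantor; the source's GTR estimates
  are unpublished) at 0.02 of the neutral rate.  That conservation scale
  gives limbed species ~98–99% identity to the root, i.e. strongly
  conserved elements, and was chosen by analysing the detector's null:
  at this divergence a spurious ≤ 14/20 window in an intact species has
  probability ~1e-4 per species-element, low enough that single-species
  lineages (minimum 1) recover planted combination tables exactly at
  cohort scale.  Element lengths are uniform on 60–400 bp — inside the
  30–3,371 bp range of real catalogues, sized for desk-scale runs.
- **Planted degeneration.** Substitution bursts rewrite an affected
  window to an exact target identity (default 0.5) against the true root
  sequence, verified by re-measurement before acceptance; deletions
  write ≥ 50 contiguous gap columns (columns are never removed, so the
  shared frame survives, as an aligner would show a loss).  The default
  cohort plan assigns lineage combinations in fixed proportions (40%
  intact; the rest singles, pairs — snake+caecilian most common —
  triples and one quadruple class), planting one species more than each
  lineage minimum.
- **Feature fixtures.** Genes with TSSs at controlled distances
  (including a 999,999 / 1,000,001 bp boundary pair), limb genes placed
  preferentially near snake+caecilian convergent elements (80% vs 10%),
  enhancer tracks whose scores straddle the −log10 p = 2 cutoff,
  ortholog tables for 14 reference + 3 large-genome species with exactly
  49 genes limited-expansion in all three (set sizes 127/323/327), and
  outgroup presence matrices drawn to match known origin labels.

One RNG stream per run is forked per operation name (CRC32 of the name
mixed into the seed), so adding an operation never perturbs earlier
draws; identical seeds give byte-identical outputs.

What the generator does **not** emulate: realistic indel length
distributions, rate heterogeneity across sites or lineages, alignment
error, assembly artefacts, GC-content structure, or correlated gene
locations.  Passing tests therefore demonstrate that the implementation
applies the stated criteria exactly and recovers planted truth under
idealised evolution — not that the thresholds have any particular
sensitivity or specificity on real whole-genome alignments.

## Statistics

Fisher tests are two-sided by probability-mass summation (the R
convention), with the sample odds ratio ad/bc and a Haldane–Anscombe
(+0.5) variant reported whenever a cell is zero.  FDR control is
Benjamini–Hochberg throughout.  Term enrichment is upper-tail
hypergeometric over flat annotation sets (no ontology-graph
propagation).  Group comparisons use Welch's unequal-variance t-test.
Region-set enrichment counts elements, not base pairs, with the full CNE
set as the universe.  The limb-gene overlap test counts CNEs as units
(consistent with the CNE background); a gene-unit variant is a flag
away.

The Monte Carlo overlap test draws each gene set independently and
uniformly without replacement, 100,000 trials by default (the demo
config uses 20,000), and shares its intersection routine with the
observed-data path.  The empirical p is add-one smoothed,
(x + 1)/(n + 1), so it is never exactly zero; the raw exceedance count
is reported alongside.  The universe size N is a required input: the
screen's Z-score depends on it, and no default could be justified.
Per-gene "intron length" is the total across the gene (a per-intron
median variant sits behind a flag).

## Numerical and boundary choices

All printed thresholds are read strictly as printed: length "more than
30 bp" means ≥ 31; exon deviation "> 40%" excludes the boundary; "less
than twice the median" excludes 2×; enhancer scores must strictly exceed
2; the 1 Mb gene radius is inclusive.  Species "presence" in the
retention filter means ≥ 1 non-gap non-N column (the weakest sensible
reading, configurable).  The exon-deviation filter rejects a gene when
*any* species deviates, so a single universe survives for the overlap
screen.  Gene–element distance is measured from the nearest element
edge to the TSS point.  Zero-variance groups in Welch comparisons take
the degenerate limit (t = 0, p = 1 when means coincide).  Elapsed time
for neutral simulation is the path from the compared ancestor node,
approximated per species by its time since limb loss in the bundled
pipeline.

## Problem sizes

The shipped runs use a 40-element demo cohort (CLI), a 500-element
validation cohort (planted-truth recovery), 1,000 random elements for
the detector-vs-enumeration equivalence check, 20,000 Monte Carlo trials
for the overlap null, and 10 neutral replicates per element — sizes at
which every planted signal is comfortably detectable while a full run
stays in the minutes range on one core.

## Known limitations

- Parsimony underestimates ancestral divergence on long branches; with
  the strongly conserved elements simulated here the root is recovered
  at ≥ 98% identity, but on fast-evolving elements a likelihood
  reconstruction would differ.
- The detector's any-window rule means sensitivity grows with element
  length under planted whole-element bursts; boundary behaviour is
  therefore validated on constructed single-window instances.
- The neutral contrast treats each element's replicates as independent
  observations, as the source design does; no within-element clustering
  correction is applied.
- Liftover, alignment construction, orthology inference and raw
  conserved-element calling are out of scope: their outputs are inputs
  here.
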