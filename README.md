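# limbloss

Detection and analysis of **degenerated conserved noncoding elements
(dCNEs)** in limbless tetrapods — snakes, caecilians and limbless lizards
— against their limbed relatives.

## The problem

Conserved noncoding elements (CNEs) are candidate regulatory sequences
kept nearly intact across limbed tetrapods.  When limbs are lost, CNEs
that exist to pattern limbs come under relaxed selection and decay.
Because limb loss happened independently in several lineages (caecilians
~192 Mya, snakes ~170 Mya, and two limbless-lizard lineages ~40 and
~35 Mya), elements that degenerate *convergently* — in two or more of
those lineages at once — are strong candidates for ancestral limb
regulatory elements.  This package implements the computational core of
that comparative design as a tested, reusable library with a synthetic
data generator, so every stage runs and is validated without any genome
downloads.

## What it computes

For each CNE alignment over 31 limbed + 12 limbless species, with the
tetrapod-ancestor sequence reconstructed by Fitch parsimony (gaps as a
fifth state):

- **Degeneration calls.** A limbless species is degenerated in an element
  if some window over the ancestor's ungapped positions satisfies either
  criterion: (i) a 20 bp window (1 bp steps) where ≥ 29 limbed species
  keep ≥ 18/20 matches to the ancestor while the focal species keeps
  ≤ 14/20; or (ii) a 50 bp window where ≥ 29 limbed species keep ≥ 30/50
  matches and the focal species is entirely absent (gap).
- **Lineage calls and convergence.** A lineage is degenerated with ≥ 3
  snakes, ≥ 2 caecilians, or 1 species for single-species lineages; the
  convergence class of an element is the number of degenerated lineages.
  Per-species degeneration rates are convergent-element counts divided by
  time since limb loss (Myr).
- **CNE catalogue filters**: coding-region subtraction, length > 30 bp,
  ≥ 29 limbed species present; genes linked within 1 Mb of their TSS.
- **Enrichment statistics**: two-sided Fisher tests of dCNE-associated
  genes against limb-gene lists over the full CNE background,
  element-level region-set enrichment, hypergeometric term enrichment,
  Benjamini–Hochberg FDR.
- **Neutral contrast**: GTR simulation of each element over the same
  elapsed time at the full neutral rate (d = rate × Myr per site,
  matrix-exponential transition probabilities, 10 replicates/element),
  compared with observed identity by Welch t-tests.
- **Intron-expansion screen**: genes whose total intron length in three
  large-genome species stays below twice the 14-species reference median,
  with a 100,000-trial Monte Carlo null for the three-way overlap
  (Z-score and add-one-smoothed empirical p).
- **Annotation layers**: enhancer activity (scored track overlap with
  −log10 p > 2), pleiotropy (active in ≥ 2 tissues), evolutionary origin
  (deepest outgroup genome retaining the element), and convergent
  amino-acid sites with conserved flanks.

## Worked example

The whole pipeline runs from one config and one seed:

```bash
limbloss --config tests/data/demo_config.yaml --seed 1 --out-dir demo run-all
```

which prints, stage by stage:

```
simulated 40 elements for 43 species
reconstructed 40 elements (0 skipped)
retained 40 elements, 25 gene links
117 degenerated species-element calls
24 dCNEs, 12 convergent
tested 6 lineage combinations
neutral contrast written
shared limited-expansion genes: 49 (z=7.03)
pleiotropic fraction: 0.636
demo/summary.json
```

Reading the output: of 40 simulated elements, 24 are degenerated in at
least one lineage and 12 convergently in ≥ 2; the snake+caecilian
combination carries the planted limb-gene signal (its Fisher q ≈ 2e-6 in
`demo/enrich/limb_gene_enrichment.tsv` while all other combinations stay
non-significant); the intron screen recovers exactly the 49 genes planted
as limited-expansion in all three large-genome species, about 7 null
standard deviations above the Monte Carlo mean; and 63.6% of
enhancer-active elements are active in two or more tissues.  The
`demo/summary.json` file aggregates these numbers; identical config +
seed reproduce it byte for byte.

Library use mirrors the CLI:

```python
from limbloss.synthetic import build_demo_tree, make_validation_cohort
from limbloss.ancestors import reconstruct_ancestors
from limbloss.detection import scan_set, call_lineages, classify_convergence
from limbloss.datamodel import DetectionConfig

species, tree = build_demo_tree(seed=1)
alns, truth, combos = make_validation_cohort(species, tree, n_cnes=100, seed=1)
recon = [reconstruct_ancestors(a, tree) for a in alns]
calls = scan_set(recon, species, DetectionConfig())
records, summary = classify_convergence(call_lineages(calls, species, DetectionConfig()))
print(summary["combination_counts"])
```

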