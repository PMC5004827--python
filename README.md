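# matriline

Haplotype, diversity, network and distance-dating analyses for aligned
mitochondrial control-region sequences.

`matriline` targets the standard desk analysis of a recently radiated
species group sampled at a single matrilineal locus (the fast-evolving
mtDNA control region, the classic marker for splits younger than a few
million years — e.g. the South American *Lycalopex* foxes). From one
aligned multi-FASTA plus a sample-metadata table it computes:

* **Haplotypes and sites** — exact-match haplotype classes over the
  retained columns, variable and parsimony-informative site counts,
  base composition, cross-species haplotype sharing.
* **Diversity indices** — gene diversity
  `h = [n/(n−1)](1 − Σ pᵢ²)` with Nei's analytic variance (optionally a
  resampling variance), and nucleotide diversity π as the mean per-site
  pairwise Kimura 2-parameter (K2P) distance with a bootstrap SE over
  alignment columns.
* **K2P distances and dating** — `d = −½ln(1−2P−Q) − ¼ln(1−2Q)` with
  P/Q the transition/transversion difference proportions; between-group
  divergence `d_xy` (mean over all between-group pairs, column-bootstrap
  SE, CI = ±2SE) inverted through the clock relation **d_xy = 2μT** with
  a slow/mean/fast rate triple (defaults
  2.02×10⁻⁸ / 3.68×10⁻⁸ / 5.34×10⁻⁸ subst/site/year, the canid
  control-region calibration) to give conservative age intervals.
* **Median-joining network** — minimum spanning network relaxed by a
  tolerance ε, plus inferred median vectors (Steiner intermediates),
  exported as GraphML/DOT/TSV.
* **Tree, monophyly and "swap" detection** — neighbor-joining tree on
  K2P distances (Newick output), per-species monophyly tests on tree or
  network, and detection of individuals whose matriline clusters inside
  another species (field misidentification or mtDNA introgression),
  tiered by agreement of tree and network evidence.
* **Synthetic data** — a generator that grafts star or Kingman
  within-species genealogies onto a known species tree, evolves
  sequences under a K2P mutation process (rate μ, ts/tv ratio κ), can
  plant introgressed matrilines, and records full ground truth, so every
  stage is testable without downloads.

## Worked example

```python
from matriline import (RateCalibration, date_divergence, group_divergence,
                       make_fixture)

alignment, metadata, truth = make_fixture("six_species_radiation")
by = metadata.by_species()
div = group_divergence(alignment, by["culpaeus"], by["griseus"],
                       n_bootstrap=1000, seed=0)
age = date_divergence(div, RateCalibration())
print(f"d_xy = {div.d_xy:.4f} ± {div.se:.4f}")
print(f"t_mid = {age.t_mid:,.0f} y  [{age.t_low:,.0f} – {age.t_high:,.0f}]")
```

prints

```
d_xy = 0.0284 ± 0.0061
t_mid = 385,688 y  [152,445 – 1,002,278]
```

The fixture's true culpaeus–griseus split is 366,000 y: the point
estimate `d_xy/(2μ)` lands ~5% high on this single 588-bp realization
and the ±2SE interval, evaluated with the fast rate on the low bound and
the slow rate on the high bound, comfortably brackets the truth. The
`examples/` directory holds one short narrative script per capability
(haplotypes/diversity, network, dating, introgression detection,
simulation); each prints the numbers it computes and what they mean.

A thin CLI wraps the same library calls:

```bash
matriline simulate --fixture introgression_6 --outdir data/
matriline analyze --fasta data/alignment.fasta --metadata data/metadata.tsv \
                  --outdir results/ --seed 1
matriline report --outdir results/
```

`analyze` writes the full report bundle (haplotype table, diversity TSV,
GraphML network, Newick tree, swap report, dating table, JSON summary
with every parameter and seed) and is byte-reproducible for a fixed
config.

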