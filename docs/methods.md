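# Methods

This note documents the models, estimators and numerical choices behind
`matriline`, and what the synthetic-data generator does and does not
emulate.

## Input model and column filtering

All analyses operate on an aligned set of homologous mtDNA
control-region sequences. Input is case-insensitive; extended IUPAC
ambiguity codes (R, Y, …) are mapped to N with a logged count, and the
gap character `-` is treated as missing data, never as a fifth state —
control-region indels are alignment artifacts more often than
characters at this divergence scale. The default filter is *complete
deletion*: every column containing N or `-` in any sequence is removed
before analysis, and the removed 1-based column indices are reported.
This makes haplotype identity an exact string equality and keeps every
downstream statistic on a common column set. A `pairwise` mode defers
missing-data handling to the distance kernel (per-pair deletion of
incomparable columns) for sensitivity analyses. Filtering is
idempotent, and which columns of a raw amplicon to exclude is treated
as a reproducible rule, not as the recovery of any particular published
column set.

## Haplotypes and site statistics

A haplotype is an exact-match equivalence class over the retained
columns; ids are assigned in order of first appearance, so input order
affects labels but never the partition. A column is *variable* iff it
carries ≥ 2 states and *parsimony-informative* iff ≥ 2 states are each
carried by ≥ 2 sequences; hence informative ⊆ variable always. Base
composition is computed over all retained cells of all individuals by
default; because published counts sometimes collapse to unique
haplotypes first, a `haplotypes` basis is available and both can be
reported.

## Diversity indices

Gene diversity is the unbiased estimator
`h = [n/(n−1)](1 − Σ pᵢ²)` with haplotype frequencies `pᵢ`; its
standard error defaults to Nei's analytic variance

    V(h) = 2/[n(n−1)] · { 2(n−2)[Σpᵢ³ − (Σpᵢ²)²] + Σpᵢ² − (Σpᵢ²)² }

and a resampling SE (n individuals redrawn with replacement,
conventionally 10,000 times, seeded) can be requested where a
permutation-style variance is preferred; the two agree closely except
at very small n.

Nucleotide diversity π is the mean per-site pairwise distance over all
unordered pairs in the sample, K2P by default with `p` and JC69 kernels
available for the invariant suite (π_p ≤ π_K2P always, since the
correction inflates distances). Its SE is the standard deviation of π
over nonparametric bootstrap resamples of alignment columns (default
1000 replicates, seeded) — sites, not individuals, are the resampling
unit, matching the way the estimator averages over columns.

## Distances and divergence dating

The K2P distance is `d = −½ln(1−2P−Q) − ¼ln(1−2Q)` with P and Q the
proportions of compared columns differing by a transition (A↔G, C↔T)
and a transversion respectively. When `1−2P−Q ≤ 0` or `1−2Q ≤ 0` the
correction is undefined (saturation); such pairs abort the computation
with an error naming the pair rather than being silently dropped, since
silent omission biases group means downward. At `Q = 2P` — the split
expected under equal rates — K2P reduces exactly to JC69.

Between-group divergence `d_xy` is the raw mean K2P distance over all
between-group pairs (the conventional "between group mean distance");
an optional *net* variant subtracts the mean within-group diversity,
`d_A = d_xy − (π_a + π_b)/2`, as a sensitivity analysis. The SE is a
column bootstrap as above and the confidence interval is ±2SE.

Dating inverts the clock relation `d_xy = 2μT`. The rate calibration is
a (slow, mean, fast) triple — defaults
2.02×10⁻⁸, 3.68×10⁻⁸, 5.34×10⁻⁸ substitutions/site/year, the canid
control-region calibration spanning the rate estimate's 95% interval.
The point age uses the mean rate; deliberately, the *low* d_xy bound is
paired with the *fast* rate and the *high* bound with the *slow* rate,
which yields the widest (most conservative) age interval. A negative
lower d_xy bound is clamped to zero and logged. Dating is exactly
linear in d_xy and inversely proportional to μ.

## Median-joining network

Construction follows the two-step median-joining heuristic. First a
minimum spanning network over observed haplotypes: edge (u, v) with
Hamming weight d(u, v) is kept iff `d(u,v) ≤ minimax(u,v) + ε`, where
minimax(u, v) — computed as the largest edge on the MST path — is the
connection cost at which the two components first meet. At ε = 0 this
is precisely the union of all MSTs, so the network always contains a
spanning tree of true MST weight, and edge sets grow monotonically in
ε (default ε = 0; all columns weighted 1, as no weighting scheme is
assumed).

Then, iteratively, every node triple carrying at least two of its three
links (the standard cost-bounding restriction) proposes the per-column
majority-consensus median. At columns where all three states differ no
new state is invented: the candidate copies the state of the triplet
member closest to the other two (ties by lexicographic node id), and
the event is logged. Two admissibility rules depart from the plain
heuristic, both forced by invariants the network must satisfy:

1. a candidate median is accepted only if it is a true Steiner point of
   its triple — on the Hamming geodesic of all three pairs. Off-geodesic
   quasi-median fallbacks can otherwise *lengthen* shortest paths
   between observed haplotypes after the MSN is rebuilt, which would
   misrepresent observed divergences;
2. after convergence and pruning, the network is completed with a
   direct edge for any observed pair whose network path exceeds its
   Hamming distance (Hamming is a metric, so no path can legitimately
   be shorter — only equal — and under homoplasy the relaxed-MST
   criterion can leave only a longer detour).

Per iteration, all novel medians within ε of the cheapest connection
cost are added and the MSN rebuilt; iteration stops at a fixpoint or at
`max_iter` (default 20, flagged on the output if hit). Medians that lie
on no minimal observed-to-observed connection, or of degree < 2, are
pruned. Processing order is fully deterministic (sorted node ids).
On homoplasy-free data the result is a strict tree.

## NJ tree, monophyly and swap detection

The topology surface is a neighbor-joining tree on the K2P haplotype
distance matrix — a deliberate desk-scale stand-in for full Bayesian
phylogenetics, adequate for monophyly and placement questions at this
divergence scale but carrying no posterior support. Joins are
tie-broken on the lexicographically smallest id pair; negative branch
lengths are clamped to zero with the slack moved to the sister branch
(total conserved) and logged. An optional site-bootstrap reports clade
frequencies, for reporting only. NJ on additive distances recovers the
generating tree exactly (tested against an independent NJ
implementation).

A species is monophyletic on the tree iff some edge bipartition
isolates exactly its haplotypes, and on the network iff its observed
haplotypes form one connected component once other species' observed
haplotypes are removed (inferred medians may mediate); a haplotype
shared across species defeats monophyly in either mode.

Swap detection flags individuals whose matriline clusters inside
another species. Each individual's neighbourhood votes by majority
species label: on the tree, the smallest enclosing clade containing
other individuals (grown until ≥ 3 voters when its own species is
absent, which breaks the 1-vs-1 symmetry of an individual paired with a
single swapped neighbour); on the network, the co-carriers of its
haplotype or the nearest observed haplotypes by weighted shortest path,
with the same shell-growing rule. A flag is *confirmed* when tree and
network agree on the same foreign species and *tentative* otherwise —
support tiers are a proxy for the posterior-probability statements a
Bayesian analysis would make, and are documented as such. Flagged
individuals are relabelled and detection iterates to a fixpoint, so
clusters of several swapped individuals cannot shield one another; a
final validation sweep re-votes every flag under the converged labels
and drops flags that were artefacts of voting order. Individuals whose
species has a single sampled individual are never flagged (insufficient
evidence).

## Synthetic-data generator

The generator emulates the study design the package is meant for: a
small radiation (splits ~0.3–2 My), per-site rate μ = 3.68×10⁻⁸/year,
~588 bp alignments, 1–35 individuals per species, star-like
within-species expansion, and optional mtDNA introgression.

*Genealogy.* Sampled lineages coalesce bottom-up along an ultrametric
species tree (newick, branch lengths in years). Within a species the
default is a *star*: all lineages join a single ancestor at the
expansion time (default 100,000 y, clamped below the parent split) —
chosen so the implied within-species π ≈ 2μt ≈ 0.007 sits inside the
0.005–0.023 range typical of control-region data from expanding
populations. A Kingman `coalescent` mode (expected pairwise coalescence
time θ in years) is available and continues into ancestral populations.
In star mode ancestral populations coalesce instantly at each
species-tree node, so E[d_xy] = 2μT exactly and dating recovery tests
are calibration-free.

*Introgression* is modelled as complete matriline replacement (mtDNA is
one non-recombining locus): the affected recipient individuals' lineages
re-attach inside the donor species' genealogy at the stated event time,
onto a uniformly chosen donor branch spanning that time (in coalescent
mode they simply join the donor pool). Field labels stay with the
recipient species — that mismatch is the point — and the truth table
records the donor. An event older than the donor–recipient split is a
config error.

*Mutation.* Sequences evolve from a stationary-uniform random root by
per-branch Poisson mutation counts (rate μ per site per year) placed on
uniform random sites; a mutation is a transition with probability
κ/(κ+2), else one of the two transversions, i.e. the K2P process with
equal base frequencies — chosen to match the analysis model so recovery
tests are internally consistent. κ defaults to 4, a realistic
mammalian control-region value. The realized transition:transversion
count ratio converges to κ/2, and the truth object records total
mutations and the number of sites hit more than once (the homoplasy
count used to verify tree-shaped-network premises). Not emulated:
recombination, selection, among-site rate heterogeneity (Γ), indels,
base-compositional bias — so passing tests demonstrate correctness of
the estimators under their own model, not robustness to real-data
violations such as mutational hotspots (which depress the control
region's apparent divergence at deep splits).

All randomness flows through one seeded generator; identical configs
give byte-identical FASTA/metadata/truth files. Registered fixtures:
`two_species_clean` (12+12 individuals, 1 My split),
`six_species_radiation` (118 individuals across six species, basal
split 1.353 My, youngest 0.366 My), and `introgression_6` (the same
radiation with six recipient individuals carrying donor matrilines from
a 20 ky hybridization).

## Problem sizes and reproducibility

Default report settings (1000 column-bootstrap replicates, analytic h
variance) process the 118-individual fixture end-to-end in well under a
minute; the dating-recovery experiment in `scripts/acceptance.py` uses
50 replicates of 10+10 individuals at 588 bp, enough to put the Monte
Carlo error of the mean recovered age near 1.5% (per-replicate d_xy at
this depth carries ~10–20% stochastic error, dominated by the shared
trunk mutations). The pipeline records every parameter and seed in its
JSON summary and re-runs byte-identically.

## Known limitations

* The NJ tree is an unsupported point estimate; "strongly placed" claims
  require the Bayesian machinery this package deliberately omits.
* d_xy dating assumes a strict clock and a single calibration; rate
  uncertainty enters only through the slow/fast triple.
* The ε-relaxed MSN plus deterministic quasi-median approximation does
  not reproduce every topology of the original median-joining software,
  whose unstated settings make exact agreement untestable; cluster
  composition, MST containment and the geodesic guarantees above are
  the tested surface.
* Swap detection is a label-consistency heuristic: with only one
  sampled individual in a species, or reciprocal swaps of entire
  species, it is (correctly) silent or ambiguous.
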