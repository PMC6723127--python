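# Methods

`radmap` builds a chromosome-level scaffold map for a draft genome
assembly from RAD-seq genotypes of a single outbred F1 family (two
parents, N offspring). This note records the statistical model, the
algorithmic choices, the synthetic-data generator, and the known limits
of what the desk-scale simulations can and cannot demonstrate.

## The cross and the dropout model

At a biallelic SNP in an outbred F1 family the informative parental
cross-types are `aa×ab`, `ab×bb`, `ab×ab` and `aa×bb`. RAD-seq
genotypes at modest depth suffer allelic dropout: a true heterozygote
is sampled on only one allele and is called homozygous. We model a
single global per-direction dropout probability `e` (total 2e), giving
offspring genotype-count distributions

| cross-type | P(aa) | P(ab) | P(bb) |
|---|---|---|---|
| aa×ab | 0.5 + e/2 | 0.5 − e | e/2 |
| ab×bb | e/2 | 0.5 − e | 0.5 + e/2 |
| ab×ab | 0.25 + e/2 | 0.5 − e | 0.25 + e/2 |
| aa×bb | e | 1 − 2e | e |

The per-locus likelihood is the multinomial `Σ n_g log p_g`. A single
`ê` is profiled over all loci jointly (each locus contributing its
best cross-type), by a 0.005-step grid over [0, 0.5] followed by
bounded scalar refinement. Loci are then classified at `ê`, and
impossible offspring genotypes are corrected to heterozygotes (`bb` at
an `aa×ab` locus, `aa` at an `ab×bb` locus, both homozygotes at
`aa×bb`). `ab×ab` loci admit all three genotypes, so no correction is
possible there; they are classified and distortion-tested but excluded
from mapping.

Segregation distortion is screened with an exact two-sided binomial
test of the two permitted classes against 1:1 (single-het types), a
chi-square goodness of fit against 1:2:1 (`ab×ab`, df 2), and `p = 1`
by convention for `aa×bb` (no segregating classes). Loci with
`p < 0.05` are removed; no multiple-testing correction is applied,
matching the original workflow. Finally, loci whose observed parental
genotype pair contradicts the ML cross-type are removed; loci with a
missing parent are kept but flagged "unoriented" (they cannot be
assigned to a sex map).

## Filters

Six depth/balance filters run in a fixed cascade, each with the strict
removal boundaries of the source protocol (a value at the printed
threshold survives):

- **A, pre-genotyping:** pooled per-base depth kept inside
  `round(10^2.0) ≤ d ≤ round(10^3.2)` (100–1585 reads). Integer bounds
  are used because read counts are integers; this also makes the
  boundary behaviour exact at the printed log10 cutoffs.
- **B, locus allele balance:** pooled `log2(ref/alt)` inside
  [−2.32, 2.6]; the window is deliberately asymmetric toward the
  reference allele (reference alignment bias).
- **C, locus total depth:** pooled depth inside [320, 1400].
- **D, genotype depth:** per-call depth inside [8, 40], else MISSING.
- **E, heterozygote balance:** het calls with `|log2(ref/alt)| > 3.26`
  (or an allele at zero reads) set MISSING.
- **F, missingness:** loci with fewer than 50 called offspring of the
  nominal 90 removed. (An alternative reading — at most 40 missing —
  is available via `missingness_counts_missing`; the two coincide at
  the nominal design.)

Filters D–E only ever mask calls; the audit records loci, called
offspring genotypes and percent missing after every step.

## Recombination fractions and grouping

For two pseudo-testcross markers heterozygous in the same parent,
offspring are recoded het/hom and the two-point recombination fraction
is the phase-minimised discordance `rf = min(d, n−d)/n` over the `n`
co-called offspring; estimates with `n < 20` are treated as unknown.

Residual dropout biases this estimator upward: after the
impossible-genotype correction only the "legal homozygote" direction
survives, flipping a het/hom state with probability `q = e/2` per
offspring and inflating observed discordance to about
`r(1−2q)² + 2q(1−q)`. Because `ê` is already estimated, the pipeline
inverts this relation (`debias_dropout`, on by default):
`r̂ = (D − 2q(1−q)) / (1−2q)²`, clipped to [0, 0.5]. At `e = 0.05`
the raw noise floor is ≈0.049 — most of the 0.07 clustering budget —
and without the correction the 24 chromosomes fragment into ~36
groups; with it they are recovered exactly.

Scaffolds are clustered by single linkage on the mean inter-scaffold
rf (threshold 0.07): a scaffold joins a group if it links to *any*
member, i.e. groups are the connected components of the thresholded
graph. Unknown entries count as unlinked. Scaffolds whose
position-ordered markers form two internally linked (<0.07) but
mutually unlinked (>0.3) blocks of ≥2 markers are flagged as putative
chimeras — reported, never split. Loci linking to two or more groups
(or unlinked to their own while linked to another) are excluded.
Markers are then thinned to the 5 most complete per scaffold per
cross-type class, and loci that appear as single-locus double
crossovers within a scaffold (an offspring state disagreeing with both
called flanks) in ≥1 individual are removed.

## Ordering, distances, and the consensus map

Marker-by-marker seriation is unreliable at family scale: with ~40–90
co-called meioses per pair, truly separated marker pairs show an
observed rf of exactly 0 by sampling alone (probability ≈0.4 for
adjacent scaffolds at the default simulation scale). A
sum-of-adjacent-rf (SARF) local search will chain such spurious zero
edges and can reach a SARF *below the true order's* while scrambling
the map. Two design choices address this:

1. **Whole-scaffold anchoring.** Within each linkage group and parent,
   markers of one scaffold are phase-aligned and majority-voted into a
   single consensus het/hom state per offspring. Voting raises the
   per-scaffold call rate far above any single marker's and cancels
   isolated dropout miscalls. Scaffolds are ordered as units; this is
   the same reasoning that leads consensus anchoring tools to treat
   scaffolds, not markers, as the unit of placement.
2. **Spectral seriation.** The scaffold backbone order is the Fiedler
   vector of the similarity graph (0.5 − rf), which uses each
   scaffold's full distance profile and cannot tunnel through a single
   spurious zero. `order_markers` (the general seriation entry point)
   uses the same spectral construction followed by 2-opt that only
   accepts moves improving SARF by ≥0.005 — one recombinant in ~90
   meioses is ≈0.011, so smaller "improvements" are sampling noise.
   Two rounds of order-conditioned cleaning follow: an offspring state
   disagreeing with both agreeing flanks is flipped (a sub-centimorgan
   double crossover is overwhelmingly a residual dropout miscall), and
   missing states between agreeing flanks are imputed.

Markers are then seriated within each scaffold (ties broken by a hash
of the locus id, so no assembly-coordinate information leaks into the
genetic order) and each scaffold's internal direction is glued to its
neighbours by paired end-marker discordance on the shared offspring
subset. Genetic distances use Haldane's map function
`d = −50 ln(1 − 2r)` (Kosambi available), consistent with the
simulator's no-interference crossovers. Within-scaffold cM jumps
require ≥2 noise-corrected recombinant observations; a single
discordant offspring is indistinguishable from one dropout event.

The two sex-specific maps are merged per linkage-group pair (matched
by maximal Jaccard overlap of scaffold content, directions aligned by
Spearman correlation of shared scaffold positions). Each scaffold's
consensus position is the equal-weight mean of its per-map positions;
per-map positions are average ranks of the scaffold's mean cM, so
scaffolds a parent cannot separate stay exactly tied and the other
parent's map decides their order. Orientation is the sign of the
Spearman correlation between marker bp and per-map-centred genetic
position pooled over both maps; scaffolds without within-scaffold
genetic spread stay `?` (anchored but not oriented). Chromosome
coordinates are cumulative scaffold lengths plus a 100 bp `U` gap
(`map`/`no` linkage) in the exported AGP v2.0; a GFF liftover shifts
`+` scaffolds by their offset and reflects `−` scaffolds
(`new_start = offset + length − end + 1`, strand flipped).

## Synteny and mis-orientation triangulation

Given one-to-one ortholog positions in the focal species A and a
comparator B, chromosomes are paired by maximal raw ortholog counts.
Translocated genes are partitioned into singletons (a lone gene whose
A-neighbours are both syntenic), co-translocated blocks (runs ≥2), and
other. Micro-inversions are maximal runs of ≥3 consecutive orthologs
whose B-rank strictly decreases (2-gene runs are indistinguishable
from local order noise). With a third species C, each block is
triangulated: delimited by a single A scaffold *and* inverted against
C → mis-orientation in A; delimited by a single B scaffold and
co-linear against C → mis-orientation in B; delimited by neither →
putative real inversion; otherwise ambiguous. Boundary tolerance is 1
gene.

## The synthetic-data generator

The generator emulates the study design end to end: a 24-chromosome
genome (5 Mb per chromosome, scaled down from ~35 Mb for desk-scale
runs) fragmented into 20 scaffolds per chromosome (Dirichlet(3)
lengths), shuffled and flipped with probability 0.5 to define the
"assembly" frame, with the inverse mapping kept as a truth AGP; 90
offspring; 5–10 RAD SNPs per scaffold; crossovers as a Poisson process
at 2.34 cM/Mb with no interference (matching Haldane); per-genotype
negative-binomial depth (pooled mean 1000 reads over the 92 samples,
dispersion 10; parents at 2.5× — they were sequenced on multiple
barcodes in the emulated design); 2% of loci in "repeat" regions with
30× depth; heterozygote allele splits binomial(d, 0.5) conditioned on
both alleles being seen; explicit dropout with probability 2e per
offspring heterozygote, realized as all reads on one allele. Cross
types are drawn at 17.5% per single-het orientation, 20% `ab×ab`, 10%
`aa×bb`.

Two deliberate simplifications keep parameter recovery well-posed:
dropout is *only* the explicit 2e mechanism (the truncated binomial
split prevents natural sampling zeros from masquerading as dropout, so
`e = 0` really means zero correctable genotypes), and dropout keeps
the genotype's total depth (dropout via literal read loss would push
most dropout genotypes below the depth-8 filter and make the realized
dropout rate depend on depth, not on `e`). Consequences for realism:
real data mix depth-driven and restriction-site dropout, have
bimodal coverage (paired-end mass), sequencing-error base calls and
paralogous alignments; passing the recovery tests shows the estimator
is correct *under its own model*, not that `e` is identifiable in
arbitrary real data.

## What the desk-scale simulations show — and what they cannot

At the default scale each chromosome spans only ~11.7 cM, so 90
offspring contribute ~10.5 informative meioses per parent per
chromosome for 20 scaffolds: about one crossover per scaffold gap, and
an rf estimation noise sd (~0.01–0.02 at n≈85) larger than the 0.006
adjacent-gap signal. Under these conditions:

- Global dropout-rate recovery (|ê − e| ≤ 0.02), exact 24/24 linkage
  group recovery, and zero corrections at `e = 0` are all met.
- Scaffold *order* recovery plateaus near mean per-chromosome
  |Kendall tau| ≈ 0.7–0.85. This is an information limit, not an
  implementation artifact: an oracle given perfect, complete
  transmission states and the same mean-position merge reaches only
  tau ≈ 0.88, and five different seriation algorithms plateau
  together. On a longer-chromosome fixture (2 × 20 Mb) where each gap
  carries several crossovers, per-map scaffold order is recovered at
  |rho| ≥ 0.9 and total map length matches 2.34 cM/Mb within sampling
  error.
- Scaffold *orientation* evidence is 1–2 recombinant offspring per
  scaffold against a comparable residual-dropout noise rate, so the
  pipeline orients conservatively (most scaffolds stay `?`, mirroring
  the anchored-vs-oriented distinction in real maps) and orientation
  accuracy at the default dropout level remains near chance for the
  few scaffolds that are oriented. With `e = 0` the oriented subset is
  small but accurate.

## Numerical and degenerate-input conventions

All genomic coordinates are 1-based inclusive. Ties everywhere break
deterministically (enumeration order for cross-types; position then
locus id for thinning; lexicographic ids elsewhere), so identical
inputs and seed give byte-identical outputs. rf ≥ 0.5 is clamped to
0.49 with a warning before the map function; unknown adjacent rf
contributes 0 cM. Single-marker linkage groups map to 0 cM;
single-position scaffolds are anchored unoriented. The empty-survivor
cascade is a hard error advising threshold review. Seeds and a config
hash are stamped in every output header.
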