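# Methods

This note records the models behind each stage, the defaults that
matter, and the choices made where the design was genuinely open.

## Synthetic panels

The simulator emulates the situation the analyses are built for: two
deeply diverged clades ("S" and "N") in secondary contact, with
hybrid, triploid and clonal offspring, observed through a diploid
genotype caller.

**Locus classes.** Of `n_loci` biallelic SNPs, a fraction `prop_fixed`
is reciprocally fixed between the clades (the diagnostic signal: the
clades carry opposite alleles with certainty), `prop_shared_poly` is
polymorphic within clades with ALT frequencies drawn independently per
clade from Beta(0.5, 0.5) — a U-shaped site-frequency spectrum typical
of neutral polymorphism — and any remainder receives a single
Beta(0.5, 0.5) frequency shared by both clades (undiverged ancestral
polymorphism).  Defaults `prop_fixed = 0.33, prop_shared_poly = 0.67`
describe the divergence regime in which roughly a third of segregating
sites are clade-diagnostic.  Loci are placed uniformly on the declared
chromosomes; positions are 1-based in VCF output and half-open 0-based
internally.  When an inversion interval is declared, loci inside it are
forced into the reciprocally fixed class (recombination suppression
between orientations), with the `prop_fixed` quota allocated
preferentially inside the interval.

**Pedigrees.** Gametes are drawn per locus independently (no linkage —
see limitations).  F1 = one haploid gamete from a random S parent plus
one from a random N parent; F2 = gametes from two independently formed
F1s; backcrosses = an F1 gamete plus a parental gamete; triploids = an
*unreduced* F1 gamete (both haplotypes, hence one S and one N allele at
every fixed locus) plus a normal haploid N gamete.  Clonal ramets copy
their source's dosages exactly; error and missingness are applied
independently per ramet afterwards.

**Reads and calls.** Depth is Poisson(`mean_depth`, default 30 — typical
resequencing coverage); ALT read counts are Binomial(DP, p) with
`p = (d/ploidy)(1−e) + (1−d/ploidy)e` for dosage `d` and per-read
miscall rate `e` (default 0.001).  Diploids are emitted with their true
dosage; triploids are genotyped as a diploid caller would see them —
heterozygous when the variant-read fraction lies in `[0.2, 0.8]`
(inclusive; configurable), homozygous otherwise, missing at DP = 0.
Genotype error (default 0.002 per call) perturbs the emitted dosage by
one step (het ↔ hom), never directly between opposite homozygotes,
matching how joint callers actually err; missingness (default 0.02)
drops GT and AD jointly.

**Chloroplast panels.** Two star-like clusters of haploid genotype
strings: the cluster centers differ at exactly `steps_between` sites and
every other haplotype carries 1..`intra_steps` private mutations at
sites disjoint from all others, so the minimum inter-cluster Hamming
distance is exactly `steps_between` by construction.  Default sequence
length is 427 sites (a realistic complete-case chloroplast SNP panel).

**What is not emulated.** Linkage disequilibrium, recombination maps,
coalescent genealogies, selection, base-quality models, and
reference-bias artifacts.  Passing tests therefore demonstrate that the
statistics behave correctly under their own model assumptions, not that
they are robust to LD or alignment artifacts in real panels.

## Clone detection

Shared heterozygosity is a Dice coefficient over heterozygous calls,
computed on loci genotyped in both samples; the clone threshold default
is 0.9.  Fixed differences (opposite homozygotes) must not exceed
`max_fixed_diff_frac` (default 0.001) of compared loci — clone mates
differ only by genotyping error.  Clone pairs are merged by connected
components (single linkage): chains through intermediate ramets with
missing data are common, at the cost that a single spurious edge can
merge two genets — the full pairwise table is emitted so calls can be
audited.  Representatives minimise the missing rate, ties broken by
sample id.

## Ploidy from variant read frequency

At a heterozygous diploid site the expected VRF is 0.5; a triploid
carrying one or two ALT copies gives 1/3 or 2/3.  The estimator uses
heterozygous calls with DP ≥ 10 (below that the achievable fractions
are too coarse — at DP 6 the nearest values straddle 1/3), requires at
least 500 qualifying sites, histograms VRF into width-0.02 bins tiling
[0, 1], and smooths with a Gaussian kernel of two bins before taking
the modal bin.  Decision rule: DIPLOID when the mode is within 0.07 of
0.5 and neither the 1/3 nor 2/3 region reaches half the modal height;
TRIPLOID when the mode is within 0.07 of 1/3 or 2/3, or both secondary
regions exceed half the height at 0.5; anything else — including
tetraploid-like modes near 1/4 or 3/4, which are outside the model
space — is AMBIGUOUS.

A concentration gate precedes any call: the modal smoothed height must
be at least 1.5× the mean smoothed height.  A structureless profile
(uniform VRF) has a ratio near 1.1 and must not be called just because
its argmax lands near 1/3 by chance; genuine allele-balance peaks stay
above 1.5× even when a triploid's mixed 1/3 + 2/3 mass spreads broadly
at depth ~20.  Calls are deterministic given the profile and invariant
to REF/ALT relabeling (which maps the histogram to its mirror image).

## Hybrid classification

Diagnostic loci are ascertained where one parental group's ALT
frequency is ≥ 1 − `freq_tol` while the other's is ≤ `freq_tol`
(default `freq_tol = 0`, strict reciprocal fixation; a small tolerance
absorbs genotyping error in real panels), with per-group missingness
≤ 0.2.  Note that in finite parental samples, loci polymorphic in the
population can appear fixed by sampling; ascertainment is defined on
the observed panel, as it must be in practice.

Per sample: `F_He = n_He / n_All` over called diagnostic loci; hybrid
index `h` = fraction of S-clade alleles; interclass heterozygosity `H`
equals `F_He` on a strictly fixed panel and is reported separately
because the (h, H) triangle is defined in those terms.  All (h, H)
points lie inside the triangle with vertices (0,0), (1,0), (0.5,1) by
construction.  Classification: F1 when `F_He > 0.99` (the printed
anchor for first-generation hybrids) and `h ∈ [0.4, 0.6]`; pure parent
when `h` is within 0.05 of an extreme and `F_He < 0.05`; LATER_GEN for
intermediate `(h, H)` (each sexual generation past F1 halves expected
`H`); TRIPLOID_SUSPECT when `0.8 < F_He ≤ 0.99` *and* the read-balance
module calls the sample triploid — through diploid calls a triploid's
1/3-VRF sites are occasionally called homozygous, so its `F_He` is high
but incomplete, and its `h` is biased toward 0.5.  SNP thinning (one
SNP per 3000-bp window, keeping the least-missing SNP, ties by lowest
position, windows anchored at position 1) is available to decorrelate
loci before triangle computation.

## Inversion genotyping

Genotypes restricted to the interval are mean-imputed per SNP (for the
PCA only, never written back), centred and decomposed by SVD.  PC1 is
clustered by 1-D k-means with k fixed at 3 (two orientations plus
heterozygotes — no model selection) and deterministic initialisation at
the 10th/50th/90th percentiles; the middle cluster is HET.  The HET
cluster must show higher mean region heterozygosity than both
homozygote clusters, otherwise every call is flagged low-confidence.
Labels are invariant to PC1 sign flips and sample order up to the
arbitrary A/B naming of the homozygote clusters.

## Distances, trees, PCA

1 − IBS uses the standard identity-by-state scoring (1 / 0.5 / 0 by
dosage mismatch) over loci called in both samples.  It is a
dissimilarity, not a metric: the triangle inequality is not asserted.
Neighbour joining is the canonical Saitou–Nei algorithm with
deterministic tie-breaking (smallest index pair among minimal Q
values); negative branch lengths are clamped to zero with the deficit
transferred to the sister branch, preserving the joined pair's
patristic distance.  Output is an unrooted Newick string (trifurcating
root, six-decimal branch lengths).  Genotype PCA is centred-only by
default; per-SNP unit-variance scaling is an option (`scale=True`),
with zero-variance SNPs dropped under scaling.

## Haplotype networks

Identical haploid genotype strings are collapsed (missing data is a
hard error: complete-case filtering is a precondition).  The network is
a minimum spanning tree by Kruskal over Hamming distances with
deterministic tie-breaking (edges sorted by steps, then haplotype ids);
in network mode, equal-weight edges that span components merged at the
same weight level are retained as alternates.  Cluster separation is
the minimum pairwise Hamming distance across the two clusters — this is
deliberately the direct pairwise quantity, not a path length through
network intermediates, and is bounded above by every inter-cluster MST
edge; both views can be read off the emitted edge list.

## Pipeline

Stages run in the order simulate/load → filter → clones → ploidy →
hybrids → inversion → structure → haplonet; clone pruning precedes all
population-level stages so redundant ramets never distort frequencies.
Every TSV carries a header naming stage, seed and parameters; a JSON
manifest records per-stage status.  All randomness derives from the
single configured seed and reruns are byte-identical.

## Problem sizes

The test suite and the reproduction script run simulations sized for a
single CPU: panels of 1 000–10 000 SNPs with 8–20 samples, 100-seed
replicate loops for recovery-rate properties, VRF anchors at 10 000
heterozygous sites and depth 30, and exhaustive spanning-tree oracles
up to 7 haplotypes.  These sizes keep every Monte-Carlo check within
tight tolerances (3 standard errors) while the full suite completes in
well under a minute.

## Known limitations

- Single-linkage clone merging can chain distinct genets through an
  intermediate sample; audit the pairwise table when SH values sit near
  the threshold.
- The hybrid index of triploids scored through diploid calls is biased
  toward 0.5; TRIPLOID_SUSPECT therefore gates on read balance, not on
  `(h, H)` position.
- Tetraploids and higher ploidies are flagged, not called.
- Ascertainment on small parental panels inflates the diagnostic set
  with sampling-fixed loci; use `freq_tol` and larger parental groups
  to control this.
- IBS distances on panels with strong missingness structure compare
  different locus sets per pair; pair-wise locus counts are reported so
  this can be checked.
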