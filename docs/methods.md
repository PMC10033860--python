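# Methods

`mhcds` implements a comparative analysis of adaptive versus neutral
genetic structure of the kind used to ask whether spatially varying
selection, balancing selection, or demography alone shapes diversity at an
immune locus.  The adaptive marker is a set of aligned coding alleles of a
class II MHC exon scored per individual as presence/absence (several loci
co-amplify, so allele copies cannot be assigned to a locus of origin); the
neutral baseline is a panel of diploid microsatellite loci typed in the
same individuals.  All statistics run equally on real tables and on the
package's synthetic studies.

## Statistical components

**Diversity.** Per population: number of distinct alleles *h*, segregating
sites *S*, nucleotide diversity π (average pairwise proportion of differing
sites, gap columns dropped pairwise so single-codon indel alleles are kept),
private alleles *P*, mean alleles per individual NaI (a heterozygosity
proxy when locus assignment is unknown; bounded by twice the assumed locus
count), and rarefied allelic richness

AR(g) = Σ_a [1 − C(N−N_a, g)/C(N, g)],

with sampling units being individuals for presence/absence data and gene
copies for diploid loci; *g* defaults to the smallest group's unit count.
Microsatellites additionally get observed heterozygosity Ho and the
unbiased expected heterozygosity He = 2n/(2n−1)·(1 − Σp²), averaged over
loci.  π weighting is configurable: `carriage` (one sequence copy per
carriage event; the default) or `unique` (each distinct allele once).  Both
are reported because programs that take a population's sequence pool as
input do not document the weighting; neither mode is asserted to be "the"
convention.

**Differentiation.** Jost's D for a pair of demes (k = 2):
H_S = 1 − (Σp₁² + Σp₂²)/2, H_T = 1 − Σ((p₁+p₂)/2)²,
D = 2(H_T − H_S)/(1 − H_S), clipped to [0, 1].  The plug-in estimator is
the default; an `unbiased` mode substitutes (nΣp̂² − 1)/(n − 1) for each
Σp² (n = carriage events for the pooled MHC allele list, gene copies for a
microsatellite locus).  Multilocus values combine locus components as
2·mean(H_T − H_S)/mean(1 − H_S) (a `mean_D` mode averages per-locus D
instead).  MHC allele frequencies from presence/absence data are
`carriage`-normalized by default — carriers of an allele over all carriage
events, treating the population's pooled allele list as one haplotypic
sample — with a `per_individual` sensitivity mode.

**Marker contrast.** The B = 5000 bootstrap resamples the pairwise D
values (the same pair indices for both markers, preserving pair coupling)
and reports the 95% percentile interval of mean(msat) − mean(MHC), plus a
normal-theory CI of the microsatellite mean and a census of MHC pairs
exceeding its upper limit (the reverse direction is also reported, since
either exceedance direction can be of interest).  A caveat this package
makes explicit: the 66 pairwise values are not independent — every
population participates in 11 pairs, and multilocus D values share
locus-level noise — so a bootstrap over pairwise values understates the
replicate-to-replicate variance of the means.  In simulations with two
structurally identical marker panels whose true differentiation is equal,
the nominal 95% interval covers zero in roughly half the replicates rather
than 95%.  Conclusions from this contrast are therefore directional
evidence, not calibrated inference; resampling individuals would repair
the coverage but requires raw-data resampling outside this design.
Relatedly, equal drift (equal F) does **not** imply equal D across markers
of different allelic richness: under the Dirichlet F-model D grows with
1 − Σp², so a 59-allele pooled locus at the same F shows much larger D
than an 8-allele microsatellite.  This is the substantive reason the
analysis contrasts markers through bootstrap distributions rather than by
comparing raw D values.

**Isolation by distance.** Great-circle distances (haversine, R =
6371.0088 km) between population coordinates; D/(1 − D) linearization with
D ≥ 0.999 capped and flagged (complete differentiation would map to
infinity; capping keeps the pair in the regression).  Mantel and partial
Mantel tests use Spearman correlation over lower triangles by default,
with the null built by jointly permuting matrix rows and columns (never
triangle entries, which are not exchangeable), 9999 permutations, one-
tailed for the directional IBD hypothesis, and add-one p-values
p = (1 + #{r* ≥ r})/(n_perm + 1).  The slope-difference test regresses the
two linearized matrices on distance and swaps the paired responses per
pair index to build a two-sided null.  MRM regresses one unfolded distance
matrix on several others with row/column permutation of the response (999
permutations by default, a runtime choice).

**Selection.** Nei–Gojobori (1986) counting: fractional synonymous sites
per codon with mutations to stop codons excluded from the position
denominators; pairwise differences averaged with equal weight over
stop-free minimal substitution pathways; proportions corrected by
Jukes–Cantor d = −¾ ln(1 − 4p/3), undefined at p ≥ ¾ and flagged.  Gapped
codons are dropped pairwise.  dN and dS are averaged over all allele
pairs; Var(dN − dS) comes from bootstrapping codon positions (the unit
that is approximately independent; allele pairs are not), and
Z = (dN − dS)/SE is referred to a one-sided normal null for positive
selection.  Partitioned runs (ABS / non-ABS / all sites) take the codon
lists as input; a representative HLA-DRB1-derived ABS list ships as an
editable data file.  At small partitions (~16 codons) the Z statistic is
conservative (the convex JC correction inflates the noisier dS — a Jensen
effect), so calibration checks are run on the full 90-codon frame.

**Supertypes.** Alleles are reduced to their amino acids at positively
selected sites, each residue encoded by the five Sandberg z-descriptors
(hydrophobicity, steric bulk, polarity, two electronic scales; shipped as
a data file with provenance in its header).  A gap at a selected site is
imputed with the site's column means.  PCA retains all components (a
rotation), k-means runs for K = 1..K_max with 50 restarts (seed forked per
K), and K is chosen from BIC(K) = n·ln(WSS_K/n) + K·ln(n) by strict argmin
(default) or an elbow rule (smallest K within `elbow_tol` of the minimum).
The BIC form is a documented convention — no standard form exists for
k-means — and with modest within-cluster noise its argmin is known to
drift above the planted K; the supertype count reported by the pipeline
should be read with the BIC curve, which is always emitted.  ST(pop) is
the number of supertypes carried by at least one individual of the
population; lineage counts pool individuals.

**Comparative models.** Climate covariates are pruned by greedy
elimination until all pairwise squared Spearman correlations are below 0.5
(the variable with the larger mean ρ² leaves first; name-order
tie-breaks).  Multinomial logit models are fitted by Newton ML with
per-predictor likelihood-ratio chi-squares (df = levels − 1); separation
triggers a clearly flagged ridge-penalized fallback.  With one observation
per population (n ≈ 12) these fits are deliberately reported with
small-sample warnings — the categorical encoding of a diversity response
must be declared by the user, since treating near-continuous counts as
categories is statistically unusual.  The population tree is Saitou–Nei
neighbor joining (lowest-index tie-break, negative branch lengths clamped
to zero and counted) on a Bhattacharyya-complement distance
1 − Σ√(p₁p₂) averaged over microsatellite loci — a bounded, simple choice
where no canonical measure exists; the measure name is logged.  PGLS uses
the tree's Brownian covariance normalized to a correlation matrix, with
Pagel's λ scaling the off-diagonal entries, so λ = 0 is exactly OLS and
λ = 1 the full tree; λ is estimated by profile ML on a 101-point grid plus
bounded refinement.  Bounds default to [0, λ_max] where λ_max is the
positive-definiteness limit (often above 1); an `unconstrained` mode
searches the whole PD interval, which is how published fits report λ
values outside [0, 1].  Raw p-values are reported alongside Holm-adjusted
ones.

## The synthetic-study generator

The generator is first-class, tested code: it is the source of ground
truth for every recovery check.  Its defaults emulate a China-scale,
12-population, 3-lineage study of a widespread bat: 10 individuals per
population, 59 aligned 270-bp coding alleles across 4 co-amplifying loci
(1–8 alleles per individual), 7 microsatellite loci with 8 alleles each,
and 4 bioclimatic covariates generated as smooth functions of latitude and
longitude plus noise.

*Frequencies.* Population allele frequencies follow the F-model —
Dirichlet with concentration (1 − F)/F around global frequencies — with a
spatially correlated multiplicative tilt exp(σ·g), g a Gaussian field over
populations with covariance exp(−d²/2ℓ²) on great-circle distance.  The
tilt makes nearby populations similar, so isolation by distance emerges
without a forward simulation.  Defaults F_mhc = 0.015, F_msat = 0.01,
σ = 0.8, ℓ = 1500 km were fixed once, before the test assertions were
frozen, by matching the generator's replicate means to the published
effect sizes this design emulates (mean pairwise D ≈ 0.45 for the MHC
marker vs ≈ 0.25 for microsatellites, MHC IBD Mantel r ≈ 0.5): with 59
alleles the F-model saturates Jost's D quickly, so study-like differentiation
requires small F with most structure carried by the spatial field.

*Sequences.* Each allele accumulates a Poisson number (mean 12) of
substitutions from a common ancestor, 60% targeted at 16 designated ABS
codons where an acceptance bias plants dN/dS ≈ ω (accept nonsynonymous
proposals always, synonymous with probability 1/ω for ω ≥ 1); background
codons are neutral.  Ten PSS codons (a subset of the ABS) are overwritten
with per-cluster amino-acid anchors drawn from a z-diverse panel, one
fixed codon per amino acid, so the K_true supertypes are exact nucleotide
clusters at the selected sites.  `cluster_separation` scales the anchors'
displacement from a per-site baseline in descriptor space: 1 plants fully
separated clusters, 0 collapses them (the degradation axis used in
recovery tests).  A configurable fraction of alleles carries a single
3-bp gap at a fixed codon, mimicking the common single-codon indels of
class II exon 2 alignments.  Within-supertype alleles are identical at the
selected sites — an idealization; real supertypes share similar, not
identical, residues, so recovery results bound the easy case.

*Climate links.* One designated variable is tied to diversity two ways:
the odds of alleles from one supertype are tilted by exp(0.75·c·z) with z
the population's standardized climate value, and each population receives
round(1.5 + 0.75·c·z) planted private alleles, pinned to a 4% pool
frequency in their home population and absent elsewhere (so planting
barely moves differentiation).  c = `climate_effect` (default 1.5, chosen
so the association is detectable at n = 12 in ≥ 80% of replicates).
`climate_effect = 0` disables both links and the regression slope of
private counts on climate is centred on zero.

*What the generator does not emulate:* mutation along a genealogy
(sequence clusters are planted, not evolved), linkage between the two
marker classes beyond shared geography, genotyping error and allelic
dropout, missing data patterns, and real bioclimatic covariance structure.
Passing recovery tests therefore shows the estimators work under the
stated model, not that any particular field dataset satisfies it.

## Numerical and design choices

- One run-level RNG is forked per stage by a named key (CRC32 of the stage
  name into a `SeedSequence` spawn key), so adding a stage never perturbs
  another stage's draws; every randomized result records its seed and
  replicate count.
- Pairwise NG86 quantities are precomputed as 61×61 codon tables; the
  codon bootstrap is a single matrix product with a multinomial count
  matrix, making 5000 replicates cheap.
- Degenerate inputs: H_S = 1 makes D undefined (reported missing); all-
  equal encodings return K = 1 with a warning; constant matrices make the
  Mantel statistic undefined (error); stop-containing or frame-breaking
  alleles are rejected at I/O with the offending record named.
- Test problem sizes (e.g. 200-replicate calibrations at 199 permutations,
  300–1000-replicate bootstraps, 10 k-means restarts) are chosen so the
  whole suite completes in about a minute on one core while keeping the
  binomial envelopes meaningful; the library defaults remain 9999/5000/50.

## Known limitations

- The pairwise-value bootstrap contrast is anticonservative (see above);
  it is reported as the field's standard procedure with its coverage
  quantified, not as a calibrated test.
- Jost's D comparisons across markers of unequal allelic richness are not
  interpretable as comparisons of drift; only within-marker structure and
  the bootstrap contrast direction are.
- The NG86 Z-test is conservative on short site partitions.
- MNL and PGLS fits at n = 12 are fragile; separation and λ estimates at
  the PD boundary are flagged rather than hidden.
- Supertype BIC selection is a convention; the emitted BIC curve, not the
  single chosen K, is the robust output.
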