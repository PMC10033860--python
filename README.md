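# mhcds

Comparative analysis of adaptive (MHC) versus neutral (microsatellite)
genetic structure across populations — for molecular ecologists asking
whether an immune locus's geographic variation reflects spatially varying
selection, balancing selection, or demography alone.

The package grew out of the standard design for class II MHC landscape
genetics in a wide-ranging vertebrate: a peptide-binding exon amplified
across several indistinguishable loci and scored per individual as a 0/1
allele-presence matrix, a panel of diploid microsatellites typed in the
same individuals, population coordinates, and bioclimatic covariates.  It
provides, as a tested library plus a thin `mhcds` CLI:

- **Diversity** — h, S, π (pairwise deletion over gap columns), private
  alleles, mean alleles per individual (NaI), and rarefied allelic
  richness AR(g) = Σ_a [1 − C(N−N_a, g)/C(N, g)]; Ho and unbiased He for
  microsatellites; per-population and pooled per-lineage.
- **Differentiation** — Jost's D from allele frequencies,
  D = [(H_T − H_S)/(1 − H_S)]·k/(k−1) with k = 2, plug-in or
  nearly-unbiased estimators, multilocus combination, and a paired
  5000-replicate bootstrap contrasting the two markers' mean pairwise D.
- **Spatial tests** — haversine distances, the D/(1−D) linearization,
  seeded Mantel / partial Mantel (Spearman, label permutation, 9999
  permutations), a slope-difference permutation test, and MRM.
- **Selection** — Nei–Gojobori/Jukes–Cantor dN/dS with stop-aware site
  counts and pathway-averaged differences, partitioned by antigen-binding
  site lists, with a codon-bootstrap Z-test of dN = dS.
- **Supertypes** — alleles encoded at positively selected sites by the
  five Sandberg z-descriptors, clustered by k-means with a BIC curve
  (argmin or elbow selection).
- **Comparative models** — Spearman-ρ² redundancy filtering, multinomial
  logit models with likelihood-ratio tests, neighbor-joining population
  trees (Newick), and PGLS with Pagel's λ (profile ML, constrained or
  unconstrained).
- **A synthetic-study generator** with known ground truth (F-model
  frequencies with a spatially correlated tilt, planted dN/dS, planted
  supertype clusters, planted climate effects), used by the test suite to
  verify that every stage recovers what was planted.

## Worked example

```python
from mhcds import SimConfig, simulate_study
from mhcds.differentiation import (bootstrap_contrast, pairwise_dest_mhc,
                                   pairwise_dest_msat)
from mhcds.spatial_stats import (geographic_distance_matrix, ibd_transform,
                                 mantel_test, partial_mantel_test)
from mhcds.selection import selection_z_test
from mhcds.supertypes import cluster_supertypes, encode_alleles

study = simulate_study(SimConfig(seed=1))      # 12 pops, 59 alleles, 7 msat loci
d_mhc = pairwise_dest_mhc(study.genotypes)
d_msat = pairwise_dest_msat(study.msat)
c = bootstrap_contrast(d_mhc, d_msat, B=5000, seed=1)
print(f"mean Dest  MHC {c.mean_mhc:.3f}   msat {c.mean_msat:.3f}")
print(f"bootstrap 95% CI of (msat - MHC): [{c.diff_ci[0]:.3f}, {c.diff_ci[1]:.3f}]")

km = geographic_distance_matrix(study.populations)
lin_mhc, _ = ibd_transform(d_mhc)
lin_msat, _ = ibd_transform(d_msat)
ibd = mantel_test(lin_mhc, km, n_perm=9999, seed=1)
pm = partial_mantel_test(lin_mhc, km, lin_msat, n_perm=9999, seed=2)
print(f"IBD Mantel r = {ibd.statistic:.3f} (p = {ibd.p_value:.4f})")
print(f"partial Mantel r (controlling msat) = {pm.statistic:.3f} (p = {pm.p_value:.4f})")

z = selection_z_test(study.catalog, study.abs_sites, n_boot=2000, seed=1)
print(f"ABS dN/dS = {z.omega:.2f}, Z = {z.z:.2f}, p = {z.p_value:.4f}")

model = cluster_supertypes(encode_alleles(study.catalog, study.pss), seed=1)
print(f"supertypes: K = {model.chosen_k}")
```

prints

```
mean Dest  MHC 0.415   msat 0.250
bootstrap 95% CI of (msat - MHC): [-0.193, -0.136]
IBD Mantel r = 0.634 (p = 0.0004)
partial Mantel r (controlling msat) = 0.451 (p = 0.0027)
ABS dN/dS = 1.79, Z = 2.52, p = 0.0059
supertypes: K = 6
```

Reading it: the adaptive marker is substantially more differentiated than
the neutral one (the bootstrap CI of the mean difference excludes zero on
the negative side), its differentiation increases with distance even after
controlling for neutral structure (partial Mantel) — the signature of
spatially varying selection rather than demography — the antigen-binding
sites carry a significant nonsynonymous excess, and the 59 alleles fall
into six functional supertypes, exactly the number planted by the
generator.

The same stages are available from the shell:

```sh
mhcds simulate --seed 1 --out fixture/
mhcds diversity --fasta fixture/alleles.fasta --mhc fixture/mhc_genotypes.tsv \
      --msat fixture/msat_genotypes.tsv --out diversity.tsv
mhcds run --seed 1 --out results/      # full pipeline, one seed
```

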