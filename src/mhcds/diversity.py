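"""Per-population and per-lineage diversity statistics for both markers.

For the adaptive marker (presence/absence allele calls): number of distinct
alleles h, segregating sites S, nucleotide diversity pi, private alleles P,
mean alleles per individual NaI (a heterozygosity proxy when locus of
origin is unknown), and rarefied allelic richness AR.  For microsatellites:
rarefied AR plus observed (Ho) and unbiased expected (He) heterozygosity.

pi and S use pairwise deletion for gap columns, so single-codon indel
alleles contribute at their ungapped sites without discarding alignment
columns globally.  pi weighting is configurable: "carriage" expands each
allele into one copy per carrier (the default reading of feeding a
population's sequence pool to a diversity program); "unique" uses each
distinct allele once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import AlleleCatalog, MhcGenotypeMatrix, MsatGenotypeTable

__all__ = [
    "nucleotide_diversity",
    "segregating_sites",
    "private_alleles",
    "mean_alleles_per_individual",
    "rarefied_allelic_richness",
    "rarefied_allelic_richness_msat",
    "msat_heterozygosity",
    "diversity_summary",
    "lineage_rollup",
]


def _seq_matrix(catalog: AlleleCatalog, allele_ids: list[str]) -> np.ndarray:
    return np.array([list(catalog.records[a]) for a in allele_ids])


def nucleotide_diversity(
    catalog: AlleleCatalog, allele_multiset: list[str]
) -> float:
    """Average pairwise proportion of differing ungapped sites.

    ``allele_multiset`` may repeat ids (one entry per carriage event).
    Columns gapped in either member of a pair are excluded for that pair.
    Returns NaN for fewer than two copies.
    """
    if len(allele_multiset) < 2:
        return float("nan")
    # collapse to unique alleles with multiplicities: pairwise distances only
    # depend on the distinct sequences.
    uniq, counts = np.unique(allele_multiset, return_counts=True)
    mat = _seq_matrix(catalog, list(uniq))
    gap = mat == "-"
    n_u = len(uniq)
    d = np.zeros((n_u, n_u))
    for i in range(n_u):
        both = ~(gap[i] | gap[i + 1 :])
        diffs = (mat[i] != mat[i + 1 :]) & both
        sites = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            d[i, i + 1 :] = np.where(sites > 0, diffs.sum(axis=1) / sites, 0.0)
    d = d + d.T
    n = counts.sum()
    # sum over ordered pairs of copies = c_i * c_j * d_ij (d_ii = 0)
    total = counts @ d @ counts / 2.0
    return float(total / (n * (n - 1) / 2.0))


def segregating_sites(catalog: AlleleCatalog, allele_set: list[str]) -> int:
    """Alignment columns with at least two distinct non-gap states."""
    mat = _seq_matrix(catalog, sorted(set(allele_set)))
    S = 0
    for col in mat.T:
        states = set(col) - {"-"}
        if len(states) >= 2:
            S += 1
    return S


def private_alleles(geno: MhcGenotypeMatrix) -> pd.Series:
    """Count of alleles whose carriers all belong to one population."""
    pops = geno.populations
    pop_arr = np.array([geno.population_of[i] for i in geno.individuals])
    out = {p: 0 for p in pops}
    for j in range(len(geno.alleles)):
        carrier_pops = set(pop_arr[geno.presence[:, j] > 0])
        if len(carrier_pops) == 1:
            out[next(iter(carrier_pops))] += 1
    return pd.Series(out, name="P")


def mean_alleles_per_individual(geno: MhcGenotypeMatrix) -> pd.Series:
    out = {}
    for p in geno.populations:
        rows = geno.rows_for(p)
        out[p] = float(rows.sum(axis=1).mean())
    return pd.Series(out, name="NaI")


def _rarefy(N: int, counts: np.ndarray, g: int) -> float:
    """AR = sum_a [1 - C(N - N_a, g) / C(N, g)] via log-gamma."""
    if g > N:
        raise ValueError(f"rarefaction depth g={g} exceeds sample size N={N}")

    def logC(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    counts = np.asarray(counts, dtype=float)
    rem = N - counts
    frac = np.where(rem >= g, np.exp(logC(rem, g) - logC(N, g)), 0.0)
    return float(np.sum(1.0 - frac))


def rarefied_allelic_richness(geno: MhcGenotypeMatrix, g: int | None = None) -> pd.Series:
    """Rarefied allele count for presence/absence data; the sampling unit is
    the individual, and g defaults to the smallest population size."""
    pops = geno.populations
    sizes = {p: geno.rows_for(p).shape[0] for p in pops}
    if g is None:
        g = min(sizes.values())
    out = {}
    for p in pops:
        rows = geno.rows_for(p)
        carriers = rows.sum(axis=0)
        carriers = carriers[carriers > 0]
        out[p] = _rarefy(rows.shape[0], carriers, g)
    return pd.Series(out, name="AR")


def rarefied_allelic_richness_msat(
    msat: MsatGenotypeTable, g: int | None = None
) -> pd.Series:
    """Rarefied allelic richness for diploid loci (unit = gene copy),
    averaged over loci; g defaults to the smallest population's complete
    gene-copy count across loci."""
    pops = msat.populations
    copy_counts = {}  # (pop, locus) -> (N copies, counts per allele)
    min_copies = np.inf
    for p in pops:
        calls = msat.calls_for(p)
        for j in range(len(msat.loci)):
            vals = calls[:, j, :].ravel()
            vals = vals[vals != 0]
            if len(vals) == 0:
                continue
            _, cnt = np.unique(vals, return_counts=True)
            copy_counts[(p, j)] = (len(vals), cnt)
            min_copies = min(min_copies, len(vals))
    if g is None:
        g = int(min_copies)
    out = {}
    for p in pops:
        vals = [
            _rarefy(N, cnt, g)
            for (pp, _), (N, cnt) in copy_counts.items()
            if pp == p and N >= g
        ]
        out[p] = float(np.mean(vals)) if vals else float("nan")
    return pd.Series(out, name="AR_msat")


def msat_heterozygosity(msat: MsatGenotypeTable) -> pd.DataFrame:
    """Observed and unbiased expected heterozygosity per population,
    averaged over loci.  He uses the (2n/(2n-1)) small-sample correction."""
    rows = {}
    for p in msat.populations:
        calls = msat.calls_for(p)
        ho_vals, he_vals = [], []
        for j in range(len(msat.loci)):
            geno = calls[:, j, :]
            complete = geno[geno[:, 0] != 0]
            if len(complete) == 0:
                continue
            ho_vals.append(float(np.mean(complete[:, 0] != complete[:, 1])))
            vals = complete.ravel()
            _, cnt = np.unique(vals, return_counts=True)
            freqs = cnt / cnt.sum()
            n2 = len(vals)  # gene copies
            he = 1.0 - np.sum(freqs**2)
            if n2 > 1:
                he *= n2 / (n2 - 1)
            he_vals.append(float(he))
        rows[p] = {
            "Ho": float(np.mean(ho_vals)) if ho_vals else float("nan"),
            "He": float(np.mean(he_vals)) if he_vals else float("nan"),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def _pop_allele_multiset(
    geno: MhcGenotypeMatrix, rows: np.ndarray, weighting: str
) -> list[str]:
    alleles = np.array(geno.alleles)
    if weighting == "carriage":
        out: list[str] = []
        for r in rows:
            out.extend(alleles[r > 0])
        return out
    if weighting == "unique":
        present = rows.sum(axis=0) > 0
        return list(alleles[present])
    raise ValueError(f"unknown pi weighting {weighting!r}")


def diversity_summary(
    catalog: AlleleCatalog,
    geno: MhcGenotypeMatrix,
    msat: MsatGenotypeTable | None = None,
    pi_weighting: str = "carriage",
    rarefaction_g: int | None = None,
) -> pd.DataFrame:
    """One row per population: h, S, pi, P, NaI, AR (and AR_msat/Ho/He when
    microsatellites are supplied)."""
    pops = geno.populations
    alleles = np.array(geno.alleles)
    h, S, pi = {}, {}, {}
    for p in pops:
        rows = geno.rows_for(p)
        present = list(alleles[rows.sum(axis=0) > 0])
        h[p] = len(present)
        S[p] = segregating_sites(catalog, present) if len(present) >= 2 else 0
        multiset = _pop_allele_multiset(geno, rows, pi_weighting)
        pi[p] = nucleotide_diversity(catalog, multiset)
    df = pd.DataFrame(
        {
            "h": pd.Series(h),
            "S": pd.Series(S),
            "pi": pd.Series(pi),
            "P": private_alleles(geno),
            "NaI": mean_alleles_per_individual(geno),
            "AR": rarefied_allelic_richness(geno, rarefaction_g),
        }
    ).loc[pops]
    if msat is not None:
        df = df.join(rarefied_allelic_richness_msat(msat))
        df = df.join(msat_heterozygosity(msat))
    df.index.name = "population"
    return df


def lineage_rollup(
    catalog: AlleleCatalog,
    geno: MhcGenotypeMatrix,
    lineage_of: dict[str, str],
    msat: MsatGenotypeTable | None = None,
    pi_weighting: str = "carriage",
    rarefaction_g: int | None = None,
) -> pd.DataFrame:
    """Diversity recomputed on pooled individuals per lineage (privateness
    and every other statistic is relative to the lineage grouping, not
    aggregated from population values)."""
    pooled = MhcGenotypeMatrix(
        individuals=geno.individuals,
        alleles=geno.alleles,
        presence=geno.presence.copy(),
        population_of={
            i: lineage_of[geno.population_of[i]] for i in geno.individuals
        },
    )
    pooled_msat = None
    if msat is not None:
        pooled_msat = MsatGenotypeTable(
            individuals=msat.individuals,
            loci=msat.loci,
            calls=msat.calls.copy(),
            population_of={
                i: lineage_of[msat.population_of[i]] for i in msat.individuals
            },
        )
    df = diversity_summary(
        catalog, pooled, pooled_msat, pi_weighting, rarefaction_g
    )
    df.index.name = "lineage"
    return df
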