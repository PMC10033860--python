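"""Allele-frequency estimation, pairwise Jost's D, and the bootstrap
framework contrasting differentiation of adaptive vs neutral markers.

Jost's D for a pair of demes (k = 2) is computed from within- and total-
heterozygosity,

    H_S = 1 - (sum p1^2 + sum p2^2) / 2
    H_T = 1 - sum ((p1 + p2) / 2)^2
    D   = (H_T - H_S) / (1 - H_S) * k / (k - 1),

with a plug-in estimator by default and an optional nearly-unbiased mode
that replaces each sum p^2 by (n * sum p^2 - 1)/(n - 1) for sample size n
(sampling units: carriage events for pooled MHC alleles, gene copies for
diploid loci).  Multilocus values combine locus components as
mean(H_T - H_S) / mean(1 - H_S) * 2 by default.

For the marker contrast, the 66 pairwise D values of each marker are
resampled jointly (paired bootstrap over pair indices) and the 95%
percentile interval of mean(msat) - mean(MHC) decides whether the markers
differ; a normal-theory CI of the microsatellite mean supports the
per-pair exceedance census.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import LabeledSymMatrix, MhcGenotypeMatrix, MsatGenotypeTable

__all__ = [
    "mhc_allele_frequencies",
    "msat_allele_frequencies",
    "jost_d_pair",
    "jost_d_components",
    "jost_d_multilocus",
    "pairwise_dest_mhc",
    "pairwise_dest_msat",
    "bootstrap_contrast",
    "BootstrapContrast",
]


def mhc_allele_frequencies(
    geno: MhcGenotypeMatrix, mode: str = "carriage"
) -> pd.DataFrame:
    """Population × allele frequency table for pooled presence/absence data.

    "carriage" (default): freq(a|pop) = carriers of a / total carriage
    events, treating the population's pooled allele list as one haplotypic
    sample.  "per_individual": each individual contributes weight 1 split
    evenly across its alleles.
    """
    pops = geno.populations
    out = np.zeros((len(pops), len(geno.alleles)))
    for i, p in enumerate(pops):
        rows = geno.rows_for(p)
        if rows.size == 0:
            raise ValueError(f"empty population {p!r}")
        if mode == "carriage":
            counts = rows.sum(axis=0).astype(float)
        elif mode == "per_individual":
            counts = (rows / rows.sum(axis=1, keepdims=True)).sum(axis=0)
        else:
            raise ValueError(f"unknown frequency mode {mode!r}")
        out[i] = counts / counts.sum()
    df = pd.DataFrame(out, index=pops, columns=geno.alleles)
    df.index.name = "population"
    return df


def mhc_sample_sizes(geno: MhcGenotypeMatrix) -> pd.Series:
    """Carriage events per population (the haplotypic sample size)."""
    return pd.Series(
        {p: int(geno.rows_for(p).sum()) for p in geno.populations}, name="n_units"
    )


def msat_allele_frequencies(
    msat: MsatGenotypeTable,
) -> dict[str, pd.DataFrame]:
    """Per-locus population × allele frequency tables (missing excluded)."""
    inventory = msat.allele_inventory()
    pops = msat.populations
    out = {}
    for j, locus in enumerate(msat.loci):
        alleles = inventory[locus]
        freqs = np.zeros((len(pops), len(alleles)))
        for i, p in enumerate(pops):
            vals = msat.calls_for(p)[:, j, :].ravel()
            vals = vals[vals != 0]
            if len(vals) == 0:
                freqs[i] = np.nan
                continue
            for k, a in enumerate(alleles):
                freqs[i, k] = np.mean(vals == a)
        out[locus] = pd.DataFrame(freqs, index=pops, columns=alleles)
    return out


def _sum_sq(p: np.ndarray, n: float | None, estimator: str) -> float:
    s = float(np.sum(p**2))
    if estimator == "plugin" or n is None:
        return s
    if estimator == "unbiased":
        if n <= 1:
            return s
        return (n * s - 1.0) / (n - 1.0)
    raise ValueError(f"unknown estimator {estimator!r}")


def jost_d_components(
    p1: np.ndarray,
    p2: np.ndarray,
    n1: float | None = None,
    n2: float | None = None,
    estimator: str = "plugin",
) -> tuple[float, float]:
    """(H_T - H_S, 1 - H_S) for one locus and one deme pair."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    s1 = _sum_sq(p1, n1, estimator)
    s2 = _sum_sq(p2, n2, estimator)
    hs = 1.0 - (s1 + s2) / 2.0
    pm = (p1 + p2) / 2.0
    # total heterozygosity uses the same per-population correction applied
    # to the cross terms implicitly through s1, s2
    st = float(np.sum(pm**2)) - (np.sum(p1**2) + np.sum(p2**2)) / 4.0 + (s1 + s2) / 4.0
    ht = 1.0 - st
    return ht - hs, 1.0 - hs


def jost_d_pair(
    p1: np.ndarray,
    p2: np.ndarray,
    n1: float | None = None,
    n2: float | None = None,
    estimator: str = "plugin",
) -> float:
    """Jost's D between two demes from frequency vectors over the union
    allele set; clipped to [0, 1], NaN when H_S = 1 exactly."""
    num, den = jost_d_components(p1, p2, n1, n2, estimator)
    if den <= 0:
        return float("nan")
    return float(np.clip(2.0 * num / den, 0.0, 1.0))


def jost_d_multilocus(
    per_locus: list[tuple[float, float]], mode: str = "components"
) -> float:
    """Combine per-locus (H_T - H_S, 1 - H_S) components across loci.

    "components": 2 * mean(H_T - H_S) / mean(1 - H_S); "mean_D": arithmetic
    mean of per-locus D values.
    """
    arr = np.asarray(per_locus, dtype=float)
    if mode == "components":
        den = np.nanmean(arr[:, 1])
        if den <= 0:
            return float("nan")
        return float(np.clip(2.0 * np.nanmean(arr[:, 0]) / den, 0.0, 1.0))
    if mode == "mean_D":
        with np.errstate(invalid="ignore", divide="ignore"):
            ds = np.clip(2.0 * arr[:, 0] / arr[:, 1], 0.0, 1.0)
        return float(np.nanmean(ds))
    raise ValueError(f"unknown multilocus mode {mode!r}")


def pairwise_dest_mhc(
    geno: MhcGenotypeMatrix,
    estimator: str = "plugin",
    freq_mode: str = "carriage",
    min_n: int = 3,
) -> LabeledSymMatrix:
    """All-pairs Jost's D on pooled MHC allele frequencies."""
    freqs = mhc_allele_frequencies(geno, freq_mode)
    sizes = mhc_sample_sizes(geno)
    pops = list(freqs.index)
    small = [p for p in pops if len(geno.rows_for(p)) < min_n]
    if small:
        import warnings

        warnings.warn(f"populations below min_n={min_n}: {small}")
    n = len(pops)
    vals = np.zeros((n, n))
    F = freqs.to_numpy()
    for i in range(n):
        for j in range(i + 1, n):
            d = jost_d_pair(F[i], F[j], sizes[pops[i]], sizes[pops[j]], estimator)
            vals[i, j] = vals[j, i] = d
    return LabeledSymMatrix(pops, vals)


def pairwise_dest_msat(
    msat: MsatGenotypeTable,
    estimator: str = "plugin",
    multilocus_mode: str = "components",
) -> LabeledSymMatrix:
    """All-pairs multilocus Jost's D for diploid microsatellite loci."""
    per_locus = msat_allele_frequencies(msat)
    pops = msat.populations
    n = len(pops)
    # gene-copy sample sizes per pop per locus
    sizes = np.zeros((n, len(msat.loci)))
    for i, p in enumerate(pops):
        calls = msat.calls_for(p)
        for j in range(len(msat.loci)):
            vals = calls[:, j, :].ravel()
            sizes[i, j] = np.sum(vals != 0)
    vals = np.zeros((n, n))
    F = {locus: df.to_numpy() for locus, df in per_locus.items()}
    for i in range(n):
        for j in range(i + 1, n):
            comps = []
            for lj, locus in enumerate(msat.loci):
                p1, p2 = F[locus][i], F[locus][j]
                if np.isnan(p1).any() or np.isnan(p2).any():
                    continue
                comps.append(
                    jost_d_components(p1, p2, sizes[i, lj], sizes[j, lj], estimator)
                )
            vals[i, j] = vals[j, i] = jost_d_multilocus(comps, multilocus_mode)
    return LabeledSymMatrix(pops, vals)


@dataclass
class BootstrapContrast:
    B: int
    seed: int
    mean_mhc: float
    mean_msat: float
    boot_means_mhc: np.ndarray
    boot_means_msat: np.ndarray
    diff_ci: tuple[float, float]  # 95% percentile CI of mean(msat) - mean(mhc)
    msat_mean_ci: tuple[float, float]  # normal-theory CI of the msat mean
    mhc_above_msat_upper: int  # MHC pairwise values above msat upper CI limit
    msat_above_mhc_upper: int  # reverse direction (see notes)
    pair_flags: pd.DataFrame = field(repr=False)

    @property
    def significant(self) -> bool:
        lo, hi = self.diff_ci
        return lo > 0 or hi < 0


def bootstrap_contrast(
    dest_mhc: LabeledSymMatrix,
    dest_msat: LabeledSymMatrix,
    B: int = 5000,
    seed: int = 0,
) -> BootstrapContrast:
    """Paired bootstrap contrast of mean pairwise differentiation.

    Each replicate draws the same pair indices (with replacement) for both
    markers, preserving the coupling of population pairs, and records the
    mean D per marker; the 95% percentile CI of the replicate-wise
    difference mean(msat) - mean(mhc) excludes 0 when the markers differ.
    """
    if dest_mhc.labels != dest_msat.labels:
        dest_msat = dest_msat.reorder(dest_mhc.labels)
    if B < 100:
        import warnings

        warnings.warn(f"B={B} bootstrap replicates is very small")
    x = dest_mhc.triangle()
    y = dest_msat.triangle()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n_pairs = len(x)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_pairs, size=(B, n_pairs))
    bm_x = x[idx].mean(axis=1)
    bm_y = y[idx].mean(axis=1)
    diff = bm_y - bm_x
    ci = (float(np.percentile(diff, 2.5)), float(np.percentile(diff, 97.5)))
    # normal-theory CI of the msat mean over pairs (Rmisc-style summary)
    se = y.std(ddof=1) / np.sqrt(n_pairs)
    tcrit = stats.t.ppf(0.975, n_pairs - 1)
    msat_ci = (float(y.mean() - tcrit * se), float(y.mean() + tcrit * se))
    se_x = x.std(ddof=1) / np.sqrt(n_pairs)
    mhc_ci = (float(x.mean() - tcrit * se_x), float(x.mean() + tcrit * se_x))
    labels = dest_mhc.labels
    iu = np.tril_indices(len(labels), k=-1)
    pair_names = [f"{labels[i]}-{labels[j]}" for i, j in zip(*iu)]
    flags = pd.DataFrame(
        {
            "dest_mhc": dest_mhc.triangle(),
            "dest_msat": dest_msat.triangle(),
        },
        index=pair_names,
    )
    flags["mhc_above_msat_upper"] = flags["dest_mhc"] > msat_ci[1]
    flags["msat_above_mhc_upper"] = flags["dest_msat"] > mhc_ci[1]
    return BootstrapContrast(
        B=B,
        seed=seed,
        mean_mhc=float(x.mean()),
        mean_msat=float(y.mean()),
        boot_means_mhc=bm_x,
        boot_means_msat=bm_y,
        diff_ci=ci,
        msat_mean_ci=msat_ci,
        mhc_above_msat_upper=int(flags["mhc_above_msat_upper"].sum()),
        msat_above_mhc_upper=int(flags["msat_above_mhc_upper"].sum()),
        pair_flags=flags,
    )
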