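"""Synthetic study generator with known ground truth.

Emulates the structure of a two-marker landscape-genetics study of a
wide-ranging bat: ~12 populations in 3 lineages on a China-scale map,
~10 individuals per population, one multi-locus MHC-like marker (59
aligned 270-bp coding alleles scored as presence/absence across 4
co-amplifying loci) and 7 diploid microsatellite loci, plus bioclimatic
covariates with planted effects.

Population allele frequencies follow an F-model: for differentiation
parameter F in (0,1), each population's frequency vector is Dirichlet
with concentration (1 - F)/F around the global frequencies, so larger F
means stronger drift.  Isolation by distance is induced by multiplying
frequencies by exp(sd * g) where g is a Gaussian random field over
populations with covariance exp(-d^2 / (2 * decay^2)) on great-circle
distance — nearby populations receive similar tilts, so differentiation
grows with distance without a forward simulation.

Sequence-level ground truth: substitutions accumulate on each allele from
a common ancestral sequence with an acceptance bias planting a target
dN/dS at designated antigen-binding-site codons; positively selected
sites (a 10-codon subset of the ABS) are overwritten with per-cluster
amino-acid anchors so that alleles form K_true groups in physicochemical
descriptor space; a fraction of alleles carries a single-codon (3-bp) gap
at a fixed codon.  A designated climate variable is linked to the count
of population-private alleles and to the presence odds of one supertype
by tilting population allele pools before genotypes are drawn.

All generators are pure functions of (config, seed); the run-level RNG is
forked per stage by a named key so adding a stage never perturbs another
stage's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import (
    AlleleCatalog,
    ClimateTable,
    LabeledSymMatrix,
    MhcGenotypeMatrix,
    MsatGenotypeTable,
    PopulationTable,
    SiteList,
)
from .selection import GENETIC_CODE, SENSE_CODONS

__all__ = ["SimConfig", "SimTruth", "SyntheticStudy", "simulate_alleles",
           "simulate_populations", "simulate_climate", "simulate_study"]

_LINEAGE_NAMES = ("NE", "CE", "SW")
_LINEAGE_CENTERS = {"NE": (43.0, 127.0), "CE": (35.0, 112.0), "SW": (25.0, 102.0)}
# one amino acid per cluster index, chosen to be well spread in z-space
_ANCHOR_PANEL = "RFDGWKELHS"
_PRIVATE_FREQ = 0.04  # pool frequency pinned for planted private alleles
_CODONS_FOR: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    _CODONS_FOR.setdefault(GENETIC_CODE[_c], []).append(_c)


def fork_rng(seed: int, key: str) -> np.random.Generator:
    """Deterministic named fork of the run seed."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(key.encode()),))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class SimConfig:
    """Study-design knobs; the defaults emulate the reference study's scale
    and published effect sizes (see the package methods note)."""

    n_pops: int = 12
    n_lineages: int = 3
    n_ind_per_pop: int = 10
    n_loci_mhc: int = 4
    n_msat_loci: int = 7
    n_msat_alleles: int = 8
    n_alleles_mhc: int = 59
    F_mhc: float = 0.015
    F_msat: float = 0.01
    distance_decay: float = 1500.0  # km, spatial correlation scale
    spatial_sd: float = 0.8  # scale of the log-frequency tilt
    climate_effect: float = 1.5  # planted private-allele slope per SD of climate
    indel_fraction: float = 0.5
    K_true: int = 6
    n_pss: int = 10
    n_abs: int = 16
    cluster_separation: float = 1.0  # anchor spread in z-space (0 collapses clusters)
    omega_abs: float = 3.0  # planted dN/dS at ABS codons
    subs_per_allele: float = 12.0
    abs_sub_fraction: float = 0.6
    indel_codon: int = 84
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pops", "n_lineages", "n_ind_per_pop", "n_loci_mhc",
                     "n_msat_loci", "n_alleles_mhc", "K_true", "n_pss", "n_abs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("F_mhc", "F_msat"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.K_true > self.n_alleles_mhc:
            raise ValueError("more clusters than alleles")
        if self.K_true > len(_ANCHOR_PANEL):
            raise ValueError(f"K_true above supported maximum {len(_ANCHOR_PANEL)}")
        if self.n_pss > self.n_abs:
            raise ValueError("PSS list must fit inside the ABS list")
        if not 0 <= self.cluster_separation <= 1:
            raise ValueError("cluster_separation must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth recorded alongside the synthetic data."""

    cluster_of: dict[str, int]
    K_true: int
    pss: list[int]
    abs_sites: list[int]
    global_freqs_mhc: pd.Series | None = None
    pop_freqs_mhc: pd.DataFrame | None = None
    pop_freqs_msat: dict[str, pd.DataFrame] | None = None
    expected_dest_mhc: LabeledSymMatrix | None = None
    expected_dest_msat: LabeledSymMatrix | None = None
    climate_variable: str | None = None
    climate_effect: float = 0.0
    planted_private_counts: dict[str, int] | None = None
    forced_private: dict[str, list[str]] | None = None
    target_cluster: int | None = None


@dataclass
class SyntheticStudy:
    catalog: AlleleCatalog
    pss: SiteList
    abs_sites: SiteList
    genotypes: MhcGenotypeMatrix
    msat: MsatGenotypeTable
    populations: PopulationTable
    climate: ClimateTable
    truth: SimTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# sequences


def _random_sense_codon(rng: np.random.Generator, exclude_stop_adjacent: bool = False) -> str:
    return SENSE_CODONS[rng.integers(0, len(SENSE_CODONS))]


def _codon_for(aa: str) -> str:
    # one fixed codon per amino acid so anchor sharing is exact at the
    # nucleotide level (synonymous wobble would blur the planted clusters
    # and dilute the nonsynonymous excess at selected sites)
    return _CODONS_FOR[aa][0]


def _apply_substitutions(
    codons: list[str],
    region: np.ndarray,
    n_subs: int,
    omega: float,
    omega_bg: float,
    rng: np.random.Generator,
) -> None:
    """Accept-reject substitution sampler planting a target dN/dS.

    Proposals are uniform single-base changes; in a region with target
    omega >= 1 every nonsynonymous proposal is accepted and synonymous
    ones with probability 1/omega (and symmetrically for omega < 1), so
    the realized nonsynonymous:synonymous ratio is tilted by omega
    relative to the neutral expectation."""
    accepted = attempts = 0
    n_codons = len(codons)
    while accepted < n_subs and attempts < 200 * n_subs + 200:
        attempts += 1
        k = int(rng.integers(0, n_codons))
        cod = codons[k]
        pos = int(rng.integers(0, 3))
        base = "ACGT"[rng.integers(0, 4)]
        if base == cod[pos]:
            continue
        mut = cod[:pos] + base + cod[pos + 1 :]
        if GENETIC_CODE[mut] == "*":
            continue
        syn = GENETIC_CODE[mut] == GENETIC_CODE[cod]
        w = omega if region[k] else omega_bg
        if w >= 1.0:
            p_accept = (1.0 / w) if syn else 1.0
        else:
            p_accept = 1.0 if syn else w
        if rng.random() < p_accept:
            codons[k] = mut
            accepted += 1


def simulate_alleles(
    config: SimConfig,
) -> tuple[AlleleCatalog, SiteList, SiteList, SimTruth]:
    """Generate the aligned allele catalog plus its PSS and ABS site lists.

    Returns (catalog, pss, abs_sites, truth); truth carries the planted
    cluster assignment."""
    rng = fork_rng(config.seed, "alleles")
    n_codons = 90
    candidates = [p for p in range(1, n_codons + 1) if p != config.indel_codon]
    abs_pos = sorted(rng.choice(candidates, size=config.n_abs, replace=False).tolist())
    pss_pos = sorted(rng.choice(abs_pos, size=config.n_pss, replace=False).tolist())
    abs_mask = np.zeros(n_codons, dtype=bool)
    abs_mask[[p - 1 for p in abs_pos]] = True

    ancestor = [_random_sense_codon(rng) for _ in range(n_codons)]
    # Per-PSS-site cluster anchors: a baseline amino acid plus K_true - 1
    # alternatives drawn from a z-diverse panel.  cluster_separation scales
    # the anchors' displacement from the baseline in descriptor space (the
    # realized anchor is the amino acid nearest the scaled target), so 1
    # plants fully separated clusters and 0 collapses them onto the
    # baseline; alleles of a cluster share their anchors exactly.
    from .supertypes import load_zscales

    ztab = load_zscales()
    anchors: dict[int, list[str]] = {}
    for p in pss_pos:
        panel = list(_ANCHOR_PANEL)
        rng.shuffle(panel)
        base = panel[0]
        site_anchors = [base]
        for k in range(1, config.K_true):
            target = ztab.loc[base] + config.cluster_separation * (
                ztab.loc[panel[k]] - ztab.loc[base]
            )
            dist = ((ztab - target) ** 2).sum(axis=1)
            site_anchors.append(str(dist.idxmin()))
        anchors[p] = site_anchors

    records: dict[str, str] = {}
    cluster_of: dict[str, int] = {}
    n_indel = int(round(config.indel_fraction * config.n_alleles_mhc))
    indel_carriers = set(
        rng.choice(config.n_alleles_mhc, size=n_indel, replace=False).tolist()
    )
    for i in range(config.n_alleles_mhc):
        allele_id = f"A{i + 1:03d}"
        cluster = i % config.K_true
        cluster_of[allele_id] = cluster
        codons = list(ancestor)
        n_subs = int(rng.poisson(config.subs_per_allele))
        # split the substitution budget between ABS and background codons
        n_abs_subs = int(rng.binomial(n_subs, config.abs_sub_fraction))
        # ABS substitutions restricted to ABS codons, background elsewhere
        sub_regions = [
            (np.flatnonzero(abs_mask), n_abs_subs, config.omega_abs),
            (np.flatnonzero(~abs_mask), n_subs - n_abs_subs, 1.0),
        ]
        for idx, count, omega in sub_regions:
            if count <= 0 or len(idx) == 0:
                continue
            sub = [codons[k] for k in idx]
            _apply_substitutions(
                sub, np.ones(len(sub), dtype=bool), count, omega, omega, rng
            )
            for k, c in zip(idx, sub):
                codons[k] = c
        # overwrite PSS codons with the cluster anchors
        for p in pss_pos:
            codons[p - 1] = _codon_for(anchors[p][cluster])
        if i in indel_carriers:
            codons[config.indel_codon - 1] = "---"
        records[allele_id] = "".join(codons)
    catalog = AlleleCatalog(records, reference_length=270)
    pss = SiteList(pss_pos, "PSS", n_codons)
    abs_sites = SiteList(abs_pos, "ABS", n_codons)
    truth = SimTruth(
        cluster_of=cluster_of, K_true=config.K_true, pss=pss_pos, abs_sites=abs_pos
    )
    return catalog, pss, abs_sites, truth


# ---------------------------------------------------------------------------
# geography and frequencies


def _place_populations(config: SimConfig, rng: np.random.Generator) -> PopulationTable:
    lineages = list(_LINEAGE_NAMES[: config.n_lineages])
    if config.n_lineages > len(_LINEAGE_NAMES):
        lineages += [f"L{k}" for k in range(len(_LINEAGE_NAMES), config.n_lineages)]
    rows = []
    for i in range(config.n_pops):
        lin = lineages[i % len(lineages)]
        if lin in _LINEAGE_CENTERS:
            lat0, lon0 = _LINEAGE_CENTERS[lin]
        else:
            lat0 = 22 + 23 * rng.random()
            lon0 = 98 + 30 * rng.random()
        rows.append(
            {
                "population": f"P{i + 1:02d}",
                "lineage": lin,
                "latitude": float(np.clip(lat0 + rng.normal(0, 2.0), -89, 89)),
                "longitude": float(lon0 + rng.normal(0, 2.5)),
                "n": config.n_ind_per_pop,
            }
        )
    return PopulationTable(pd.DataFrame(rows).set_index("population"))


def _spatial_kernel(populations: PopulationTable, decay: float) -> np.ndarray:
    from .spatial_stats import geographic_distance_matrix

    d = geographic_distance_matrix(populations).values
    if not np.isfinite(decay) or decay <= 0:
        K = np.ones_like(d)
    else:
        K = np.exp(-(d**2) / (2.0 * decay**2))
    return K + 1e-8 * np.eye(len(K))


def _f_model_freqs(
    global_freqs: np.ndarray,
    F: float,
    kernel_chol: np.ndarray,
    spatial_sd: float,
    n_pops: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Population × allele frequencies: Dirichlet((1-F)/F * global) per
    population, then a spatially correlated multiplicative tilt."""
    conc = (1.0 - F) / F
    alpha = np.maximum(global_freqs * conc, 1e-6)
    gam = rng.gamma(shape=np.tile(alpha, (n_pops, 1)))
    if spatial_sd > 0:
        g = kernel_chol @ rng.standard_normal((n_pops, len(global_freqs)))
        gam = gam * np.exp(spatial_sd * g)
    gam = np.maximum(gam, 1e-300)
    return gam / gam.sum(axis=1, keepdims=True)


def _expected_dest(freqs: np.ndarray, labels: list[str]) -> LabeledSymMatrix:
    from .differentiation import jost_d_pair

    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = jost_d_pair(freqs[i], freqs[j])
    return LabeledSymMatrix(labels, vals)


def simulate_populations(
    config: SimConfig,
    catalog: AlleleCatalog,
    truth: SimTruth | None = None,
    freq_tilt: pd.DataFrame | None = None,
) -> tuple[MhcGenotypeMatrix, MsatGenotypeTable, PopulationTable, SimTruth]:
    """Place populations, draw F-model allele frequencies for both markers
    and sample individual genotypes.

    ``freq_tilt`` (population × allele multiplicative weights) is the hook
    the climate stage uses to plant diversity effects before genotypes are
    drawn."""
    if truth is None:
        truth = SimTruth(cluster_of={}, K_true=config.K_true, pss=[], abs_sites=[])
    rng_geo = fork_rng(config.seed, "geography")
    populations = _place_populations(config, rng_geo)
    pops = populations.population_ids
    K = _spatial_kernel(populations, config.distance_decay)
    Kc = np.linalg.cholesky(K)

    rng_mhc = fork_rng(config.seed, "freqs-mhc")
    allele_ids = catalog.allele_ids
    global_freqs = rng_mhc.dirichlet(np.ones(len(allele_ids)))
    pop_freqs = _f_model_freqs(
        global_freqs, config.F_mhc, Kc, config.spatial_sd, config.n_pops, rng_mhc
    )
    if freq_tilt is not None:
        pop_freqs = pop_freqs * freq_tilt.loc[pops, allele_ids].to_numpy()
        pop_freqs = pop_freqs / pop_freqs.sum(axis=1, keepdims=True)
    if truth.forced_private:
        # pin each planted private allele to a small fixed frequency in its
        # home population and zero it elsewhere
        col = {a: k for k, a in enumerate(allele_ids)}
        for p, alleles in truth.forced_private.items():
            for a in alleles:
                pop_freqs[:, col[a]] = 0.0
        for i, p in enumerate(pops):
            mine = [col[a] for a in truth.forced_private.get(p, [])]
            if not mine:
                continue
            pop_freqs[i] /= pop_freqs[i].sum()
            pop_freqs[i] *= 1.0 - _PRIVATE_FREQ * len(mine)
            pop_freqs[i, mine] = _PRIVATE_FREQ
        pop_freqs = pop_freqs / pop_freqs.sum(axis=1, keepdims=True)

    rng_geno = fork_rng(config.seed, "genotypes-mhc")
    individuals, presence_rows, pop_of = [], [], {}
    for i, p in enumerate(pops):
        for k in range(config.n_ind_per_pop):
            ind = f"{p}_I{k + 1:02d}"
            copies = rng_geno.choice(
                len(allele_ids), size=2 * config.n_loci_mhc, p=pop_freqs[i]
            )
            row = np.zeros(len(allele_ids), dtype=np.int8)
            row[np.unique(copies)] = 1
            individuals.append(ind)
            presence_rows.append(row)
            pop_of[ind] = p
    presence = np.array(presence_rows)
    carried = presence.sum(axis=0) > 0
    geno = MhcGenotypeMatrix(
        individuals=individuals,
        alleles=[a for a, c in zip(allele_ids, carried) if c],
        presence=presence[:, carried],
        population_of=pop_of,
    )

    rng_msat = fork_rng(config.seed, "msat")
    loci = [f"L{j + 1}" for j in range(config.n_msat_loci)]
    msat_freqs: dict[str, pd.DataFrame] = {}
    calls = np.zeros((len(individuals), len(loci), 2), dtype=np.int64)
    msat_pop_of = dict(pop_of)
    for j, locus in enumerate(loci):
        labels = 100 + 2 * np.arange(config.n_msat_alleles)
        gf = rng_msat.dirichlet(np.ones(config.n_msat_alleles))
        pf = _f_model_freqs(
            gf, config.F_msat, Kc, config.spatial_sd, config.n_pops, rng_msat
        )
        msat_freqs[locus] = pd.DataFrame(pf, index=pops, columns=labels)
        for i, p in enumerate(pops):
            rows = [
                r
                for r, ind in enumerate(individuals)
                if pop_of[ind] == p
            ]
            draws = rng_msat.choice(labels, size=(len(rows), 2), p=pf[i])
            calls[rows, j, :] = draws
    msat = MsatGenotypeTable(
        individuals=list(individuals), loci=loci, calls=calls, population_of=msat_pop_of
    )

    truth.global_freqs_mhc = pd.Series(global_freqs, index=allele_ids)
    truth.pop_freqs_mhc = pd.DataFrame(pop_freqs, index=pops, columns=allele_ids)
    truth.pop_freqs_msat = msat_freqs
    truth.expected_dest_mhc = _expected_dest(pop_freqs, pops)
    locus_mats = [
        _expected_dest(df.to_numpy(), pops).values for df in msat_freqs.values()
    ]
    truth.expected_dest_msat = LabeledSymMatrix(pops, np.mean(locus_mats, axis=0))
    return geno, msat, populations, truth


# ---------------------------------------------------------------------------
# climate


def simulate_climate(
    config: SimConfig, populations: PopulationTable, truth: SimTruth
) -> tuple[ClimateTable, pd.DataFrame | None]:
    """Generate bioclimatic covariates as smooth functions of the map plus
    noise, and (for climate_effect != 0) the population × allele frequency
    tilt that plants a climate signal in private-allele counts and in one
    supertype's presence odds.

    Returns (climate_table, freq_tilt); the tilt is None when no effect is
    planted.  Truth records the designated variable, the effect size, the
    planted per-population private-allele targets and the target cluster.
    """
    rng = fork_rng(config.seed, "climate")
    lat = populations.frame["latitude"].to_numpy(float)
    lon = populations.frame["longitude"].to_numpy(float)
    pops = populations.population_ids
    frame = pd.DataFrame(
        {
            "BIO1": 28.0 - 0.65 * lat + rng.normal(0, 0.8, len(pops)),
            "BIO2": 6.0 + 0.18 * (lat - 30) + 0.05 * (lon - 110) + rng.normal(0, 0.5, len(pops)),
            "BIO12": 1800.0 - 28.0 * lat + 6.0 * (lon - 100) + rng.normal(0, 60.0, len(pops)),
            "BIO15": 55.0 + 0.8 * (lat - 30) - 0.4 * (lon - 110) + rng.normal(0, 3.0, len(pops)),
        },
        index=pops,
    )
    climate = ClimateTable(frame)
    truth.climate_variable = "BIO1"
    truth.climate_effect = config.climate_effect
    if config.climate_effect == 0:
        truth.planted_private_counts = {p: 0 for p in pops}
        return climate, None

    z = frame["BIO1"].to_numpy()
    z = (z - z.mean()) / z.std(ddof=0)
    allele_ids = [f"A{i + 1:03d}" for i in range(config.n_alleles_mhc)]
    tilt = pd.DataFrame(1.0, index=pops, columns=allele_ids)

    # supertype-presence link: alleles of cluster 0 get odds tilted by climate
    target_cluster = 0
    cluster_alleles = [a for a, c in truth.cluster_of.items() if c == target_cluster]
    for i, p in enumerate(pops):
        tilt.loc[p, cluster_alleles] = np.exp(0.5 * config.climate_effect * z[i])

    # private-allele link: reserve rare alleles as forced pop-exclusive.
    # Their frequency is pinned to a small constant downstream (truth.
    # forced_private), so planting privates barely moves differentiation.
    base = 1.5
    targets = {
        p: int(np.clip(round(base + 0.75 * config.climate_effect * z[i]), 0, 5))
        for i, p in enumerate(pops)
    }
    reserve = [a for a in allele_ids if a not in cluster_alleles]
    rng.shuffle(reserve)
    cursor = 0
    forced: dict[str, list[str]] = {p: [] for p in pops}
    for p in pops:
        take = reserve[cursor : cursor + targets[p]]
        cursor += len(take)
        forced[p] = list(take)
    truth.planted_private_counts = targets
    truth.forced_private = forced
    truth.target_cluster = target_cluster
    return climate, tilt


# ---------------------------------------------------------------------------
# orchestrator


def simulate_study(config: SimConfig) -> SyntheticStudy:
    """Run the full generator: alleles → geography → climate (tilting the
    allele pools) → genotypes."""
    catalog, pss, abs_sites, truth = simulate_alleles(config)
    rng_geo = fork_rng(config.seed, "geography")
    populations = _place_populations(config, rng_geo)
    climate, tilt = simulate_climate(config, populations, truth)
    geno, msat, populations, truth = simulate_populations(
        config, catalog, truth, freq_tilt=tilt
    )
    return SyntheticStudy(
        catalog=catalog,
        pss=pss,
        abs_sites=abs_sites,
        genotypes=geno,
        msat=msat,
        populations=populations,
        climate=climate,
        truth=truth,
        config=config,
    )
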