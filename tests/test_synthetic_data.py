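"""Ground-truth recovery and reproducibility of the study generator."""

import numpy as np
import pytest
from scipy import stats

from mhcds.io_formats import AlleleCatalog
from mhcds.synthetic_data import (
    SimConfig,
    fork_rng,
    simulate_alleles,
    simulate_climate,
    simulate_populations,
    simulate_study,
)


class TestConfig:
    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(F_mhc=1.5)
        with pytest.raises(ValueError):
            SimConfig(n_pops=0)
        with pytest.raises(ValueError):
            SimConfig(K_true=100, n_alleles_mhc=10)


class TestAlleles:
    def test_catalog_shape_and_validity(self):
        cat, pss, abs_sites, truth = simulate_alleles(SimConfig(seed=0))
        assert len(cat) == 59
        assert cat.aligned_length == 270
        assert set(pss.positions) <= set(abs_sites.positions)
        assert len(pss.positions) == 10
        # generated catalogs always satisfy io validation (constructor ran it)
        AlleleCatalog(cat.records)

    def test_small_config_cluster_structure(self):
        cat, pss, _, truth = simulate_alleles(
            SimConfig(seed=1, n_alleles_mhc=10, K_true=2)
        )
        assert len(cat) == 10
        from mhcds.supertypes import encode_alleles

        enc = encode_alleles(cat, pss)
        groups = {}
        for a in enc.index:
            groups.setdefault(truth.cluster_of[a], []).append(a)
        c0 = enc.loc[groups[0]].to_numpy()
        c1 = enc.loc[groups[1]].to_numpy()
        within = max(np.ptp(c0, axis=0).max(), np.ptp(c1, axis=0).max())
        between = np.abs(c0.mean(0) - c1.mean(0)).max()
        assert within == 0.0 and between > 0

    def test_no_indels_when_fraction_zero(self):
        cat, *_ = simulate_alleles(SimConfig(seed=2, indel_fraction=0.0))
        assert cat.indel_census() == {}

    def test_indel_fraction_respected(self):
        cat, *_ = simulate_alleles(SimConfig(seed=3, indel_fraction=0.5))
        n_gapped = sum(1 for v in cat.indel_census().values() for _ in v)
        assert n_gapped == round(0.5 * 59)

    def test_determinism(self):
        a, *_ = simulate_alleles(SimConfig(seed=4))
        b, *_ = simulate_alleles(SimConfig(seed=4))
        assert a.records == b.records


class TestPopulations:
    def test_row_sum_bounds(self, default_study):
        sums = default_study.genotypes.presence.sum(axis=1)
        assert sums.min() >= 1
        assert sums.max() <= 2 * default_study.config.n_loci_mhc
        assert sums.max() >= 4  # study-like copy-number spread

    def test_truth_frequencies_normalized(self, default_study):
        pf = default_study.truth.pop_freqs_mhc.to_numpy()
        assert np.allclose(pf.sum(axis=1), 1.0)
        for df in default_study.truth.pop_freqs_msat.values():
            assert np.allclose(df.to_numpy().sum(axis=1), 1.0)

    def test_lineage_layout(self, default_study):
        pops = default_study.populations
        assert len(pops.population_ids) == 12
        assert set(pops.frame["lineage"]) == {"NE", "CE", "SW"}

    def test_differentiation_monotone_in_F(self):
        """Realized microsatellite differentiation rises with the drift
        parameter F (replicate-averaged)."""
        from mhcds.differentiation import pairwise_dest_msat

        means = []
        for F in (0.05, 0.2, 0.4):
            vals = []
            for seed in range(3):
                cfg = SimConfig(seed=seed, F_msat=F, spatial_sd=0.0, climate_effect=0.0)
                cat, *_ , truth = simulate_alleles(cfg)
                geno, msat, pops, truth = simulate_populations(cfg, cat, truth)
                vals.append(pairwise_dest_msat(msat).triangle().mean())
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_higher_F_marker_more_differentiated(self):
        """Same marker family at two F levels: the high-F panel shows larger
        mean Jost's D in (nearly) every replicate."""
        from mhcds.differentiation import pairwise_dest_msat

        wins = 0
        for seed in range(10):
            base = dict(seed=seed, spatial_sd=0.0, climate_effect=0.0)
            cat, *_ , t1 = simulate_alleles(SimConfig(**base, F_msat=0.4))
            _, hi, _, _ = simulate_populations(SimConfig(**base, F_msat=0.4), cat, t1)
            cat2, *_ , t2 = simulate_alleles(SimConfig(**base, F_msat=0.1))
            _, lo, _, _ = simulate_populations(SimConfig(**base, F_msat=0.1), cat2, t2)
            wins += (
                pairwise_dest_msat(hi).triangle().mean()
                > pairwise_dest_msat(lo).triangle().mean()
            )
        assert wins >= 9


class TestClimate:
    def test_determinism(self, default_study):
        other = simulate_study(SimConfig(seed=11))
        assert default_study.climate.frame.equals(other.climate.frame)

    def test_planted_private_allele_signal(self):
        """Populations with higher values of the designated climate variable
        carry more private alleles (the planted association)."""
        from mhcds.diversity import private_alleles

        hits = 0
        for seed in range(10):
            s = simulate_study(SimConfig(seed=seed + 30))
            P = private_alleles(s.genotypes)
            clim = s.climate.frame[s.truth.climate_variable]
            rho, p = stats.spearmanr(P.loc[clim.index], clim)
            hits += (rho > 0) and (p <= 0.05)
        assert hits >= 8

    def test_null_effect_has_no_signal(self):
        from mhcds.diversity import private_alleles

        slopes = []
        for seed in range(25):
            s = simulate_study(SimConfig(seed=seed + 60, climate_effect=0.0))
            P = private_alleles(s.genotypes).astype(float)
            z = s.climate.frame["BIO1"]
            z = (z - z.mean()) / z.std(ddof=0)
            slopes.append(np.polyfit(z.loc[P.index], P.to_numpy(), 1)[0])
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes)) <= 2 * se + 1e-12

    def test_supertype_presence_link_recorded(self, default_study):
        truth = default_study.truth
        assert truth.target_cluster is not None
        assert truth.climate_variable in default_study.climate.frame.columns


def test_full_study_reproducible():
    a = simulate_study(SimConfig(seed=21))
    b = simulate_study(SimConfig(seed=21))
    assert a.catalog.records == b.catalog.records
    assert np.array_equal(a.genotypes.presence, b.genotypes.presence)
    assert np.array_equal(a.msat.calls, b.msat.calls)
    assert a.climate.frame.equals(b.climate.frame)


def test_named_rng_forks_independent():
    r1 = fork_rng(0, "alpha").integers(0, 2**31, 4)
    r2 = fork_rng(0, "beta").integers(0, 2**31, 4)
    r1b = fork_rng(0, "alpha").integers(0, 2**31, 4)
    assert np.array_equal(r1, r1b)
    assert not np.array_equal(r1, r2)


def test_mrm_recovers_climate_effect_on_diversity_distance():
    """Distance-matrix regression of private-allele differences on climate
    differences detects the planted effect in most replicates."""
    from mhcds.diversity import private_alleles
    from mhcds.io_formats import LabeledSymMatrix
    from mhcds.spatial_stats import covariate_distance_matrix, mrm

    hits = 0
    n_rep = 20
    for seed in range(n_rep):
        s = simulate_study(SimConfig(seed=seed + 100))
        P = private_alleles(s.genotypes).astype(float)
        pv = np.abs(P.to_numpy()[:, None] - P.to_numpy()[None, :])
        p_dist = LabeledSymMatrix(list(P.index), pv)
        cd = covariate_distance_matrix(s.climate, [s.truth.climate_variable])
        res = mrm(p_dist, {"climate": cd}, n_perm=199, seed=seed)
        hits += res.coef_p["climate"] <= 0.05
    assert hits >= int(0.8 * n_rep)
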