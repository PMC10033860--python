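"""End-to-end orchestration: simulate or load a study, then run the
analysis stages in dependency order under one seed.

Stages: diversity → differentiation (+ bootstrap marker contrast) → IBD
suite (Mantel / partial Mantel / slope difference) → selection Z-tests →
supertype clustering → climate models (MRM, MNL, NJ tree + PGLS).  Each
stage's parameters, seed and outputs are logged; a failing or disabled
stage is reported as skipped without blocking unrelated stages.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np


from . import differentiation as diff
from . import diversity as dv
from . import comparative_models as cm
from . import spatial_stats as sp
from .io_formats import write_report, write_sym_matrix
from .selection import selection_z_test
from .supertypes import cluster_supertypes, encode_alleles, supertype_profiles
from .synthetic_data import SimConfig, SyntheticStudy, simulate_study

log = logging.getLogger("mhcds")

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str | Path | None = None
    sim: SimConfig | None = None  # None -> SimConfig(seed=seed)
    stages: tuple[str, ...] = (
        "diversity",
        "dest",
        "ibd",
        "selection",
        "supertypes",
        "climate",
    )
    boot_B: int = 5000
    n_perm_mantel: int = 9999
    n_perm_mrm: int = 999
    K_max: int = 10
    n_starts: int = 50
    dest_estimator: str = "plugin"
    selection_boot: int = 1000


def _dest_stage(study: SyntheticStudy, cfg: PipelineConfig) -> dict[str, Any]:
    dest_mhc = diff.pairwise_dest_mhc(study.genotypes, cfg.dest_estimator)
    dest_msat = diff.pairwise_dest_msat(study.msat, cfg.dest_estimator)
    contrast = diff.bootstrap_contrast(
        dest_mhc, dest_msat, B=cfg.boot_B, seed=stage_seed(cfg.seed, "dest")
    )
    lineage_of = study.populations.lineage_of
    # lineage-level Dest: pool individuals per lineage
    from .io_formats import MhcGenotypeMatrix, MsatGenotypeTable

    pooled = MhcGenotypeMatrix(
        study.genotypes.individuals,
        study.genotypes.alleles,
        study.genotypes.presence.copy(),
        {
            i: lineage_of[study.genotypes.population_of[i]]
            for i in study.genotypes.individuals
        },
    )
    pooled_msat = MsatGenotypeTable(
        study.msat.individuals,
        study.msat.loci,
        study.msat.calls.copy(),
        {i: lineage_of[study.msat.population_of[i]] for i in study.msat.individuals},
    )
    return {
        "dest_mhc": dest_mhc,
        "dest_msat": dest_msat,
        "dest_mhc_lineage": diff.pairwise_dest_mhc(pooled, cfg.dest_estimator),
        "dest_msat_lineage": diff.pairwise_dest_msat(pooled_msat, cfg.dest_estimator),
        "contrast": contrast,
    }


def _ibd_stage(study, dest_mhc, dest_msat, cfg) -> dict[str, Any]:
    km = sp.geographic_distance_matrix(study.populations)
    lin_mhc, flags_mhc = sp.ibd_transform(dest_mhc)
    lin_msat, flags_msat = sp.ibd_transform(dest_msat)
    seed = stage_seed(cfg.seed, "ibd")
    mantel_mhc = sp.mantel_test(lin_mhc, km, n_perm=cfg.n_perm_mantel, seed=seed)
    mantel_msat = sp.mantel_test(lin_msat, km, n_perm=cfg.n_perm_mantel, seed=seed + 1)
    mantel_mm = sp.mantel_test(
        dest_mhc, dest_msat, n_perm=cfg.n_perm_mantel, seed=seed + 2
    )
    partial = sp.partial_mantel_test(
        lin_mhc, km, lin_msat, n_perm=cfg.n_perm_mantel, seed=seed + 3
    )
    slope = sp.slope_difference_test(
        km, lin_mhc, lin_msat, n_perm=cfg.n_perm_mantel, seed=seed + 4
    )
    return {
        "geo_km": km,
        "mantel_ibd_mhc": mantel_mhc,
        "mantel_ibd_msat": mantel_msat,
        "mantel_mhc_vs_msat": mantel_mm,
        "partial_mantel_mhc_geo_given_msat": partial,
        "slope_difference": slope,
        "capped_pairs_mhc": flags_mhc,
        "capped_pairs_msat": flags_msat,
    }


def _climate_stage(study, diversity_table, st_profile, cfg) -> dict[str, Any]:
    seed = stage_seed(cfg.seed, "climate")
    keep = cm.redundancy_filter(study.climate.frame).retained
    clim_dist = sp.covariate_distance_matrix(study.climate, keep)
    # diversity distance: absolute difference in private-allele counts
    p = diversity_table["P"].astype(float)
    pv = np.abs(p.to_numpy()[:, None] - p.to_numpy()[None, :])
    from .io_formats import LabeledSymMatrix

    p_dist = LabeledSymMatrix(list(p.index), pv)
    km = sp.geographic_distance_matrix(study.populations)
    mrm_res = sp.mrm(
        p_dist, {"climate": clim_dist, "geography": km},
        n_perm=cfg.n_perm_mrm, seed=seed,
    )
    # MNL: private-allele count (categorical) vs climate variables
    mnl_res = cm.fit_multinomial_logit(
        diversity_table["P"].astype(int).astype(str), study.climate.frame[keep]
    )
    gd = cm.genetic_distance_for_tree(study.msat)
    tree = cm.neighbor_joining(gd)
    X = study.climate.frame[keep]
    X = (X - X.mean()) / X.std(ddof=1)
    pgls_res = cm.fit_pgls(diversity_table["P"].astype(float), X, tree)
    return {
        "retained_climate_vars": keep,
        "mrm_private_vs_climate": mrm_res,
        "mnl_private_vs_climate": mnl_res,
        "nj_tree_newick": tree.newick(),
        "pgls_private_vs_climate": pgls_res,
    }


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute the configured stages on a synthetic study and return the
    results bundle (also written to ``cfg.out_dir`` when given)."""
    sim = cfg.sim or SimConfig(seed=cfg.seed)
    study = simulate_study(sim)
    results: dict[str, Any] = {
        "seed": cfg.seed,
        "sim_config": {k: getattr(sim, k) for k in sim.__dataclass_fields__},
    }
    lineage_of = study.populations.lineage_of

    def run_stage(name: str, fn):
        if name not in cfg.stages:
            results[name] = {"status": "skipped"}
            return None
        try:
            out = fn()
            results[name] = out
            return out
        except Exception as exc:  # stage isolation
            log.exception("stage %s failed", name)
            results[name] = {"status": "failed", "error": str(exc)}
            return None

    div = run_stage(
        "diversity",
        lambda: {
            "population": dv.diversity_summary(study.catalog, study.genotypes, study.msat),
            "lineage": dv.lineage_rollup(
                study.catalog, study.genotypes, lineage_of, study.msat
            ),
        },
    )
    dest = run_stage("dest", lambda: _dest_stage(study, cfg))
    if dest is not None:
        run_stage(
            "ibd",
            lambda: _ibd_stage(study, dest["dest_mhc"], dest["dest_msat"], cfg),
        )
    else:
        results["ibd"] = {"status": "skipped"}
    run_stage(
        "selection",
        lambda: {
            "ABS": selection_z_test(
                study.catalog, study.abs_sites, n_boot=cfg.selection_boot,
                seed=stage_seed(cfg.seed, "selection-ABS"),
            ),
            "non-ABS": selection_z_test(
                study.catalog, study.abs_sites.complement(), n_boot=cfg.selection_boot,
                seed=stage_seed(cfg.seed, "selection-nonABS"),
            ),
            "all": selection_z_test(
                study.catalog, None, n_boot=cfg.selection_boot,
                seed=stage_seed(cfg.seed, "selection-all"),
            ),
        },
    )
    st = run_stage(
        "supertypes",
        lambda: _supertype_stage(study, cfg),
    )
    if div is not None and st is not None:
        run_stage(
            "climate",
            lambda: _climate_stage(study, div["population"], st["profile"], cfg),
        )
    else:
        results["climate"] = {"status": "skipped"}
    if cfg.out_dir is not None:
        _write_outputs(results, study, Path(cfg.out_dir))
    return results


def _supertype_stage(study, cfg) -> dict[str, Any]:
    enc = encode_alleles(study.catalog, study.pss)
    model = cluster_supertypes(
        enc, K_max=cfg.K_max, n_starts=cfg.n_starts,
        seed=stage_seed(cfg.seed, "supertypes"),
    )
    profile = supertype_profiles(model, study.genotypes, study.populations.lineage_of)
    return {"model": model, "chosen_k": model.chosen_k, "profile": profile}


def _write_outputs(results: dict[str, Any], study, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"seed": results["seed"], "stages": {}}
    for name in ("diversity", "dest", "ibd", "selection", "supertypes", "climate"):
        val = results.get(name)
        if isinstance(val, dict) and val.get("status") in ("skipped", "failed"):
            summary["stages"][name] = val
        else:
            summary["stages"][name] = {"status": "completed"}
    dest = results.get("dest")
    if isinstance(dest, dict) and "dest_mhc" in dest:
        write_sym_matrix(dest["dest_mhc"], out_dir / "dest_mhc.tsv")
        write_sym_matrix(dest["dest_msat"], out_dir / "dest_msat.tsv")
        c = dest["contrast"]
        summary["contrast"] = {
            "mean_dest_mhc": c.mean_mhc,
            "mean_dest_msat": c.mean_msat,
            "diff_ci_low": c.diff_ci[0],
            "diff_ci_high": c.diff_ci[1],
            "B": c.B,
        }
    div = results.get("diversity")
    if isinstance(div, dict) and "population" in div:
        div["population"].to_csv(out_dir / "diversity_populations.tsv", sep="\t")
        div["lineage"].to_csv(out_dir / "diversity_lineages.tsv", sep="\t")
    ibd = results.get("ibd")
    if isinstance(ibd, dict) and "mantel_ibd_mhc" in ibd:
        summary["ibd"] = {
            "mantel_r_mhc": ibd["mantel_ibd_mhc"].statistic,
            "mantel_p_mhc": ibd["mantel_ibd_mhc"].p_value,
            "mantel_r_msat": ibd["mantel_ibd_msat"].statistic,
            "mantel_p_msat": ibd["mantel_ibd_msat"].p_value,
        }
    sel = results.get("selection")
    if isinstance(sel, dict) and "ABS" in sel:
        summary["selection"] = {
            k: {"dN": v.dN, "dS": v.dS, "omega": v.omega, "Z": v.z, "p": v.p_value}
            for k, v in sel.items()
        }
    st = results.get("supertypes")
    if isinstance(st, dict) and "chosen_k" in st:
        summary["supertypes"] = {"chosen_k": st["chosen_k"]}
        st["profile"].to_csv(out_dir / "supertype_profile.tsv", sep="\t")
    write_report(summary, out_dir / "summary.json")
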