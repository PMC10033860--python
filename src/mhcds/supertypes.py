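"""Functional clustering of MHC alleles into supertypes.

Alleles are reduced to the amino acids at positively selected codon
positions, each residue replaced by five published physicochemical
descriptors (z1 hydrophobicity, z2 steric bulk, z3 polarity, z4/z5
electronic effects).  The concatenated descriptor rows are decomposed by
PCA (all components retained), then k-means is run for K = 1..K_max and
the number of supertypes is chosen from a BIC curve,

    BIC(K) = n * ln(WSS_K / n) + K * ln(n),

either by strict argmin (default) or by an elbow rule (smallest K whose
BIC is within a tolerance of the minimum).  Supertype profiles per
population and lineage report how many functional allele classes each
group of individuals carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .io_formats import AlleleCatalog, MhcGenotypeMatrix, SiteList, ValidationError
from .selection import GENETIC_CODE

__all__ = [
    "load_zscales",
    "encode_alleles",
    "cluster_supertypes",
    "supertype_profiles",
    "SupertypeModel",
]

_WSS_FLOOR = 1e-10


def load_zscales() -> pd.DataFrame:
    """The packaged 20 × 5 z-descriptor table, indexed by one-letter code."""
    with resources.files("mhcds.data").joinpath("zscales.csv").open() as fh:
        df = pd.read_csv(fh, comment="#", index_col="aa")
    assert df.shape == (20, 5)
    return df


def encode_alleles(
    catalog: AlleleCatalog,
    pss_sites: SiteList,
    ztable: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Allele × (5 · n_sites) descriptor matrix at the selected codons.

    A gap codon at a selected position contributes that position's column
    means (mean imputation over non-gap alleles); a position gapped in
    every allele is uninformative and rejected.
    """
    if ztable is None:
        ztable = load_zscales()
    codons = catalog.codon_array()
    allele_ids = catalog.allele_ids
    cols: list[np.ndarray] = []
    names: list[str] = []
    for pos in pss_sites.positions:
        cod = codons[:, pos - 1]
        block = np.full((len(allele_ids), 5), np.nan)
        for i, c in enumerate(cod):
            if "-" in c:
                continue
            aa = GENETIC_CODE.get(c)
            if aa is None or aa == "*":
                raise ValidationError(
                    f"allele {allele_ids[i]!r}: unknown or stop codon {c!r} "
                    f"at selected site {pos}"
                )
            block[i] = ztable.loc[aa].to_numpy()
        if np.isnan(block).all():
            raise ValidationError(f"selected site {pos} is gapped in all alleles")
        col_means = np.nanmean(block, axis=0)
        nan_rows = np.isnan(block[:, 0])
        block[nan_rows] = col_means
        cols.append(block)
        names.extend(f"p{pos}_z{k + 1}" for k in range(5))
    X = np.hstack(cols)
    return pd.DataFrame(X, index=allele_ids, columns=names)


@dataclass
class SupertypeModel:
    encoded: pd.DataFrame = field(repr=False)
    pc_scores: np.ndarray = field(repr=False)
    bic_curve: pd.Series
    chosen_k: int
    assignment: pd.Series  # allele -> supertype label "ST1".."STk"
    seed: int
    selection_rule: str

    def supertype_of(self) -> dict[str, str]:
        return self.assignment.to_dict()


def cluster_supertypes(
    encoded: pd.DataFrame,
    K_max: int = 10,
    n_starts: int = 50,
    seed: int = 0,
    select: str = "argmin",
    elbow_tol: float = 1.0,
) -> SupertypeModel:
    """K-means/BIC supertype clustering of encoded alleles.

    PCA retains all components (a rotation, preserving distances), k-means
    runs with ``n_starts`` restarts per K (seed forked per K), and the BIC
    curve picks K.  Degenerate input (all rows identical) short-circuits
    to K = 1.
    """
    n = len(encoded)
    if n < K_max + 1:
        raise ValueError(f"need more than K_max={K_max} alleles, got {n}")
    X = encoded.to_numpy(float)
    if np.allclose(X, X[0]):
        import warnings

        warnings.warn("degenerate encoding: all alleles identical at selected sites")
        bic = pd.Series({1: float(n * np.log(_WSS_FLOOR))})
        assignment = pd.Series(["ST1"] * n, index=encoded.index, name="supertype")
        return SupertypeModel(encoded, X.copy(), bic, 1, assignment, seed, select)
    n_comp = min(n, X.shape[1])
    pca = PCA(n_components=n_comp, random_state=seed)
    scores = pca.fit_transform(X)
    rng = np.random.default_rng(seed)
    bic_vals: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for K in range(1, K_max + 1):
        k_seed = int(rng.integers(0, 2**31 - 1))
        if K == 1:
            centre = scores.mean(axis=0)
            wss = float(np.sum((scores - centre) ** 2))
            labels_by_k[K] = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=K, n_init=n_starts, random_state=k_seed)
            import warnings as _warnings
            from sklearn.exceptions import ConvergenceWarning

            with _warnings.catch_warnings():
                # duplicate encoded rows (alleles identical at the selected
                # sites) legitimately yield fewer distinct clusters than K
                _warnings.simplefilter("ignore", ConvergenceWarning)
                labels_by_k[K] = km.fit_predict(scores)
            wss = float(km.inertia_)
        wss = max(wss, _WSS_FLOOR)
        bic_vals[K] = float(n * np.log(wss / n) + K * np.log(n))
    bic = pd.Series(bic_vals, name="BIC")
    if select == "argmin":
        chosen = int(bic.idxmin())
    elif select == "elbow":
        thresh = bic.min() + elbow_tol
        chosen = int(min(k for k, v in bic.items() if v <= thresh))
    else:
        raise ValueError(f"unknown selection rule {select!r}")
    lbl = labels_by_k[chosen]
    # stable supertype naming: order clusters by first allele occurrence
    order: dict[int, int] = {}
    for c in lbl:
        if c not in order:
            order[c] = len(order) + 1
    assignment = pd.Series(
        [f"ST{order[c]}" for c in lbl], index=encoded.index, name="supertype"
    )
    return SupertypeModel(encoded, scores, bic, chosen, assignment, seed, select)


def supertype_profiles(
    model: SupertypeModel,
    geno: MhcGenotypeMatrix,
    lineage_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-population (and optionally per-lineage) supertype presence.

    Returns a table of populations × supertypes of 0/1 presence plus an
    ``ST`` column (count of distinct supertypes carried by at least one
    individual of the group).
    """
    missing = [a for a in geno.alleles if a not in model.assignment.index]
    if missing:
        raise KeyError(f"alleles missing from supertype model: {missing}")
    st_of = model.assignment.loc[geno.alleles].to_numpy()
    supertypes = sorted(set(model.assignment), key=lambda s: int(s[2:]))

    def profile(groups: dict[str, str]) -> pd.DataFrame:
        group_ids: dict[str, None] = {}
        for ind in geno.individuals:
            group_ids.setdefault(groups[ind], None)
        rows = {}
        for g in group_ids:
            idx = [i for i, ind in enumerate(geno.individuals) if groups[ind] == g]
            present_alleles = geno.presence[idx].sum(axis=0) > 0
            carried = set(st_of[present_alleles])
            rows[g] = {st: int(st in carried) for st in supertypes}
            rows[g]["ST"] = len(carried)
        return pd.DataFrame.from_dict(rows, orient="index")

    pop_table = profile(geno.population_of)
    pop_table.index.name = "population"
    if lineage_of is not None:
        lin_table = profile(
            {i: lineage_of[geno.population_of[i]] for i in geno.individuals}
        )
        lin_table.index.name = "lineage"
        pop_table = pd.concat([pop_table, lin_table], keys=["population", "lineage"])
    return pop_table
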