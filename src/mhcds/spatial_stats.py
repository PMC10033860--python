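"""Geographic distances and distance-matrix permutation inference:
Mantel and partial Mantel tests, the regression slope-difference test, and
multiple regression on distance matrices (MRM).

All tests operate on the lower triangles of labelled symmetric matrices
and build their null distributions by jointly permuting matrix rows and
columns (never triangle entries independently, which breaks the
exchangeability structure of distance data).  p-values use the add-one
rule p = (1 + #extreme) / (n_perm + 1) and are therefore never zero.
Isolation by distance is examined on the linearized D/(1 - D) scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import ClimateTable, LabeledSymMatrix, PopulationTable

__all__ = [
    "EARTH_RADIUS_KM",
    "geographic_distance_matrix",
    "ibd_transform",
    "mantel_test",
    "partial_mantel_test",
    "slope_difference_test",
    "mrm",
    "covariate_distance_matrix",
    "MantelResult",
    "SlopeDiffResult",
    "MrmResult",
]

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance between two WGS84 points in kilometres."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def geographic_distance_matrix(populations: PopulationTable) -> LabeledSymMatrix:
    coords = populations.coords()
    n = len(coords)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = haversine_km(*coords[i], *coords[j])
    return LabeledSymMatrix(populations.population_ids, vals)


def ibd_transform(
    dest: LabeledSymMatrix, cap: float = 0.999
) -> tuple[LabeledSymMatrix, list[str]]:
    """Elementwise D/(1 - D); D >= cap is truncated to cap first (complete
    differentiation would map to infinity) and the affected pairs flagged."""
    vals = dest.values.copy()
    n = len(dest.labels)
    flagged = []
    iu = np.tril_indices(n, k=-1)
    for i, j in zip(*iu):
        if vals[i, j] >= cap:
            flagged.append(f"{dest.labels[i]}-{dest.labels[j]}")
    capped = np.minimum(vals, cap)
    out = capped / (1.0 - capped)
    np.fill_diagonal(out, 0.0)
    return LabeledSymMatrix(dest.labels, out), flagged


# ---------------------------------------------------------------------------
# permutation machinery


def _check_labels(*mats: LabeledSymMatrix) -> list[LabeledSymMatrix]:
    ref = mats[0].labels
    out = [mats[0]]
    for m in mats[1:]:
        if m.labels != ref:
            if set(m.labels) != set(ref):
                raise ValueError("matrix label sets differ")
            m = m.reorder(ref)
        out.append(m)
    return out


def _rank_matrix(m: LabeledSymMatrix) -> np.ndarray:
    """Rank-transform the off-diagonal values in place in a symmetric
    matrix, so label permutation of the ranked matrix yields the Spearman
    null."""
    n = len(m.labels)
    iu = np.tril_indices(n, k=-1)
    ranks = stats.rankdata(m.values[iu])
    out = np.zeros_like(m.values)
    out[iu] = ranks
    out.T[iu] = ranks
    return out


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc**2).sum() * (yc**2).sum())
    if den == 0:
        raise ValueError("constant matrix: correlation undefined")
    return float((xc * yc).sum() / den)


@dataclass
class MantelResult:
    statistic: float
    p_value: float
    n_perm: int
    method: str
    tail: str


def mantel_test(
    A: LabeledSymMatrix,
    B: LabeledSymMatrix,
    method: str = "spearman",
    n_perm: int = 9999,
    seed: int = 0,
    tail: str = "upper",
) -> MantelResult:
    """Mantel correlation between two distance matrices with a row/column
    permutation null.  Spearman by default; one-tailed (positive) for the
    directional isolation-by-distance hypothesis, or "two-sided"/"lower"."""
    A, B = _check_labels(A, B)
    n = len(A.labels)
    if n < 4:
        raise ValueError("need at least 4 labels for a Mantel test")
    iu = np.tril_indices(n, k=-1)
    if method == "spearman":
        a_mat, b_mat = _rank_matrix(A), _rank_matrix(B)
    elif method == "pearson":
        a_mat, b_mat = A.values, B.values
    else:
        raise ValueError(f"unknown method {method!r}")
    x = a_mat[iu]
    r_obs = _corr(x, b_mat[iu])
    rng = np.random.default_rng(seed)
    r_perm = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        r_perm[k] = _corr(x, b_mat[np.ix_(perm, perm)][iu])
    p = _perm_p(r_obs, r_perm, tail)
    return MantelResult(r_obs, p, n_perm, method, tail)


def _perm_p(obs: float, perm: np.ndarray, tail: str) -> float:
    if tail == "upper":
        extreme = np.sum(perm >= obs)
    elif tail == "lower":
        extreme = np.sum(perm <= obs)
    elif tail == "two-sided":
        extreme = np.sum(np.abs(perm) >= abs(obs))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return float((1 + extreme) / (len(perm) + 1))


def _partial_r(rab: float, rac: float, rbc: float) -> float:
    den = np.sqrt((1 - rac**2) * (1 - rbc**2))
    if den == 0:
        raise ValueError("degenerate partial correlation (|r| = 1 with control)")
    return float((rab - rac * rbc) / den)


def partial_mantel_test(
    A: LabeledSymMatrix,
    B: LabeledSymMatrix,
    C: LabeledSymMatrix,
    method: str = "spearman",
    n_perm: int = 9999,
    seed: int = 0,
    tail: str = "upper",
) -> MantelResult:
    """Partial Mantel correlation of A and B controlling for C.

    The statistic is the first-order partial correlation over (ranked)
    triangles; the null permutes A's labels, recomputing r_AB and r_AC
    while r_BC stays fixed.
    """
    A, B, C = _check_labels(A, B, C)
    n = len(A.labels)
    iu = np.tril_indices(n, k=-1)
    if method == "spearman":
        a_mat, b_mat, c_mat = _rank_matrix(A), _rank_matrix(B), _rank_matrix(C)
    else:
        a_mat, b_mat, c_mat = A.values, B.values, C.values
    b, c = b_mat[iu], c_mat[iu]
    rbc = _corr(b, c)
    a = a_mat[iu]
    r_obs = _partial_r(_corr(a, b), _corr(a, c), rbc)
    rng = np.random.default_rng(seed)
    r_perm = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        ap = a_mat[np.ix_(perm, perm)][iu]
        r_perm[k] = _partial_r(_corr(ap, b), _corr(ap, c), rbc)
    p = _perm_p(r_obs, r_perm, tail)
    return MantelResult(r_obs, p, n_perm, method, tail)


@dataclass
class SlopeDiffResult:
    slope_a: float
    slope_b: float
    difference: float
    p_value: float
    n_perm: int


def slope_difference_test(
    x: LabeledSymMatrix | np.ndarray,
    yA: LabeledSymMatrix | np.ndarray,
    yB: LabeledSymMatrix | np.ndarray,
    n_perm: int = 9999,
    seed: int = 0,
) -> SlopeDiffResult:
    """Permutation test of equal regression slopes of two distance responses
    on a shared predictor.

    The null swaps, independently per pair index, the (yA, yB) values
    between the two groups; two-sided p on |slope_A - slope_B|.
    """

    def tri(v):
        return v.triangle() if isinstance(v, LabeledSymMatrix) else np.asarray(v, float)

    xv, ya, yb = tri(x), tri(yA), tri(yB)
    if xv.var() == 0:
        raise ValueError("zero variance in predictor")

    def slope(y):
        return float(np.cov(xv, y, ddof=1)[0, 1] / np.var(xv, ddof=1))

    sa, sb = slope(ya), slope(yb)
    d_obs = sa - sb
    rng = np.random.default_rng(seed)
    d_perm = np.empty(n_perm)
    for k in range(n_perm):
        swap = rng.random(len(xv)) < 0.5
        ya_p = np.where(swap, yb, ya)
        yb_p = np.where(swap, ya, yb)
        d_perm[k] = slope(ya_p) - slope(yb_p)
    p = _perm_p(d_obs, d_perm, "two-sided")
    return SlopeDiffResult(sa, sb, float(d_obs), p, n_perm)


@dataclass
class MrmResult:
    coefficients: dict[str, float]
    coef_p: dict[str, float]
    r_squared: float
    f_statistic: float
    overall_p: float
    n_perm: int


def mrm(
    response: LabeledSymMatrix,
    predictors: dict[str, LabeledSymMatrix],
    n_perm: int = 999,
    seed: int = 0,
    standardize: bool = False,
) -> MrmResult:
    """Multiple regression of one distance matrix on several others.

    OLS on unfolded lower triangles; significance by joint row/column
    permutation of the response matrix, recomputing coefficients and R²
    each replicate (two-sided on |coefficient|, upper tail on R² for the
    overall test).
    """
    names = list(predictors)
    mats = _check_labels(response, *predictors.values())
    response, preds = mats[0], mats[1:]
    n = len(response.labels)
    iu = np.tril_indices(n, k=-1)
    X = np.column_stack([m.values[iu] for m in preds])
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    cond = np.linalg.cond(np.column_stack([np.ones(len(X)), X]))
    if cond > 1e8:
        import warnings

        warnings.warn(f"predictors nearly collinear (condition number {cond:.2g})")
    Xd = np.column_stack([np.ones(len(X)), X])
    pinv = np.linalg.pinv(Xd)
    hat = Xd @ pinv

    y_mat = response.values

    def fit(y):
        beta = pinv @ y
        yhat = Xd @ beta
        ss_res = np.sum((y - yhat) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        return beta, r2

    y = y_mat[iu]
    beta_obs, r2_obs = fit(y)
    p_mod = X.shape[1]
    dof = len(y) - p_mod - 1
    f_obs = (r2_obs / p_mod) / ((1 - r2_obs) / dof) if dof > 0 and r2_obs < 1 else np.inf
    rng = np.random.default_rng(seed)
    beta_perm = np.empty((n_perm, p_mod))
    r2_perm = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        yp = y_mat[np.ix_(perm, perm)][iu]
        b, r2 = fit(yp)
        beta_perm[k] = b[1:]
        r2_perm[k] = r2
    coef_p = {
        name: _perm_p(beta_obs[1 + i], beta_perm[:, i], "two-sided")
        for i, name in enumerate(names)
    }
    overall_p = _perm_p(r2_obs, r2_perm, "upper")
    return MrmResult(
        coefficients=dict(zip(names, map(float, beta_obs[1:]))),
        coef_p=coef_p,
        r_squared=float(r2_obs),
        f_statistic=float(f_obs),
        overall_p=overall_p,
        n_perm=n_perm,
    )


def covariate_distance_matrix(
    table: ClimateTable | "object",
    variables: list[str] | None = None,
    metric: str = "euclidean",
) -> LabeledSymMatrix:
    """Euclidean distance between population covariate vectors after
    z-standardizing each variable (so affine rescaling of raw variables
    cannot change the matrix).  With a single variable the distance reduces
    to the absolute standardized difference."""
    import pandas as pd

    frame = table.frame if hasattr(table, "frame") else table
    if variables is None:
        variables = list(frame.columns)
    missing = [v for v in variables if v not in frame.columns]
    if missing:
        raise KeyError(f"variables not in table: {missing}")
    Z = frame[variables].to_numpy(float)
    sd = Z.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (Z - Z.mean(axis=0)) / sd
    if metric == "euclidean":
        from scipy.spatial.distance import squareform, pdist

        vals = squareform(pdist(Z))
    elif metric == "abs":
        if Z.shape[1] != 1:
            raise ValueError("metric 'abs' needs exactly one variable")
        vals = np.abs(Z[:, [0]] - Z[:, [0]].T)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return LabeledSymMatrix(list(frame.index), vals)
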