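"""Variable redundancy filtering, multinomial logit models with
likelihood-ratio tests, neighbor-joining trees from population genetic
distances, and phylogenetic generalized least squares with Pagel's lambda.

These are the "comparative" stages: they relate per-population MHC
diversity summaries and supertype profiles to climatic covariates while
controlling for non-independence induced by population history (the
microsatellite NJ tree supplies the covariance structure; lambda scales
its strength, with 0 collapsing PGLS to OLS and 1 the full Brownian
expectation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import LabeledSymMatrix, MsatGenotypeTable

__all__ = [
    "redundancy_filter",
    "RedundancyFilterResult",
    "fit_multinomial_logit",
    "MnlResult",
    "neighbor_joining",
    "PopulationTree",
    "genetic_distance_for_tree",
    "fit_pgls",
    "PglsResult",
    "holm_bonferroni",
]


# ---------------------------------------------------------------------------
# redundancy filter


@dataclass
class RedundancyFilterResult:
    retained: list[str]
    dropped: list[tuple[str, float]]  # (variable, rho^2 that removed it)
    threshold: float


def redundancy_filter(
    table: pd.DataFrame, variables: list[str] | None = None, threshold: float = 0.5
) -> RedundancyFilterResult:
    """Greedy multicollinearity pruning on squared Spearman rank correlation.

    While any retained pair has rho² >= threshold, drop the member with the
    larger mean rho² against all other retained variables (ties broken by
    variable name order).  Constant variables have undefined rho and are
    dropped up front with a warning.
    """
    if variables is None:
        variables = list(table.columns)
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    retained = sorted(variables)
    dropped: list[tuple[str, float]] = []
    const = [v for v in retained if table[v].nunique() <= 1]
    if const:
        import warnings

        warnings.warn(f"constant variables dropped: {const}")
        for v in const:
            retained.remove(v)
            dropped.append((v, float("nan")))
    while len(retained) >= 2:
        rho = table[retained].corr(method="spearman").to_numpy() ** 2
        np.fill_diagonal(rho, 0.0)
        if rho.max() < threshold:
            break
        mean_rho = rho.mean(axis=1)
        # candidates: variables in the worst pair; drop the one with larger
        # mean rho² (name order on exact ties via the pre-sorted list)
        i, j = np.unravel_index(np.argmax(rho), rho.shape)
        victim = i if mean_rho[i] >= mean_rho[j] else j
        dropped.append((retained[victim], float(rho[i, j])))
        del retained[victim]
    return RedundancyFilterResult(retained, dropped, threshold)


# ---------------------------------------------------------------------------
# multinomial logit


@dataclass
class MnlResult:
    lr_tests: pd.DataFrame  # per predictor: LR chi2, df, p
    aic: float
    coefficients: pd.DataFrame
    converged: bool
    penalized: bool


def _mnl_fit(y_codes: np.ndarray, X: np.ndarray):
    """Newton fit of a multinomial logit via statsmodels; returns (llf,
    params, converged)."""
    import statsmodels.api as sm

    model = sm.MNLogit(y_codes, X)
    with np.errstate(all="ignore"):
        try:
            res = model.fit(method="newton", maxiter=200, disp=False)
            converged = bool(res.mle_retvals.get("converged", False)) and np.isfinite(
                res.llf
            )
            return float(res.llf), np.asarray(res.params), converged
        except Exception:
            return float("nan"), None, False


def _mnl_ridge_llf(y_codes: np.ndarray, X: np.ndarray, alpha: float = 1.0):
    """Penalized fallback for separated fits: ridge multinomial logistic via
    scikit-learn, reporting the unpenalized log-likelihood at the shrunken
    coefficients."""
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=1.0 / alpha, max_iter=2000)
    clf.fit(X[:, 1:] if X.shape[1] > 1 else np.zeros((len(X), 1)), y_codes)
    prob = clf.predict_proba(X[:, 1:] if X.shape[1] > 1 else np.zeros((len(X), 1)))
    ll = float(np.sum(np.log(np.clip(prob[np.arange(len(y_codes)), y_codes], 1e-12, 1))))
    return ll, clf.coef_


def fit_multinomial_logit(
    response: pd.Series, predictors: pd.DataFrame
) -> MnlResult:
    """Multinomial log-linear model with per-predictor likelihood-ratio tests.

    Each predictor's LR chi-square compares the full model with the model
    omitting that predictor; df = (response levels - 1).  With very small n
    (the comparative stage typically has one observation per population) a
    small-sample warning is emitted, and separation triggers a clearly
    flagged ridge-penalized fallback.
    """
    y, levels = pd.factorize(response, sort=True)
    if len(levels) < 2:
        raise ValueError("response needs at least 2 levels")
    names = list(predictors.columns)
    n = len(response)
    if n < len(levels) + len(names):
        import warnings

        warnings.warn(
            f"n={n} is small for {len(levels)} levels and {len(names)} predictors"
        )
    X_full = np.column_stack([np.ones(n), predictors.to_numpy(float)])
    llf_full, params, converged = _mnl_fit(y, X_full)
    penalized = False
    if not converged:
        import warnings

        warnings.warn("MNL did not converge (separation?); ridge fallback used")
        llf_full, params = _mnl_ridge_llf(y, X_full)
        penalized = True
    k_params = (len(levels) - 1) * X_full.shape[1]
    aic = -2 * llf_full + 2 * k_params
    rows = []
    for i, name in enumerate(names):
        X_red = np.delete(X_full, 1 + i, axis=1)
        llf_red, _, conv_red = _mnl_fit(y, X_red)
        if not conv_red:
            llf_red, _ = _mnl_ridge_llf(y, X_red)
        lr = max(0.0, 2.0 * (llf_full - llf_red))
        df = len(levels) - 1
        rows.append(
            {"predictor": name, "lr_chisq": lr, "df": df, "p_value": float(stats.chi2.sf(lr, df))}
        )
    coef = (
        pd.DataFrame(
            params,
            index=["intercept"] + names if params is not None and len(params) == len(names) + 1 else None,
        )
        if params is not None
        else pd.DataFrame()
    )
    return MnlResult(
        lr_tests=pd.DataFrame(rows).set_index("predictor"),
        aic=float(aic),
        coefficients=coef,
        converged=converged,
        penalized=penalized,
    )


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class _Node:
    name: str | None
    children: list[tuple["_Node", float]] = field(default_factory=list)

    def newick(self) -> str:
        if not self.children:
            return self.name or ""
        inner = ",".join(f"{c.newick()}:{l:.10g}" for c, l in self.children)
        return f"({inner})"


@dataclass
class PopulationTree:
    """Unrooted NJ tree held rooted-for-bookkeeping at its final join."""

    root: _Node
    labels: list[str]
    clamped_branches: int = 0

    def newick(self) -> str:
        return self.root.newick() + ";"

    def _leaf_paths(self) -> dict[str, list[tuple[_Node, float]]]:
        paths: dict[str, list[tuple[_Node, float]]] = {}

        def walk(node: _Node, acc: list[tuple[_Node, float]]):
            if not node.children:
                paths[node.name] = acc
                return
            for child, length in node.children:
                walk(child, acc + [(child, length)])

        walk(self.root, [])
        return paths

    def leaf_distance_matrix(self) -> LabeledSymMatrix:
        """Patristic (path-length) distances between leaves."""
        paths = self._leaf_paths()
        n = len(self.labels)
        vals = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                pi = paths[self.labels[i]]
                pj = paths[self.labels[j]]
                k = 0
                while k < min(len(pi), len(pj)) and pi[k][0] is pj[k][0]:
                    k += 1
                d = sum(l for _, l in pi[k:]) + sum(l for _, l in pj[k:])
                vals[i, j] = vals[j, i] = d
        return LabeledSymMatrix(self.labels, vals)

    def vcv(self, labels: list[str] | None = None) -> np.ndarray:
        """Brownian covariance: shared root-to-tip path length per leaf pair."""
        paths = self._leaf_paths()
        labels = labels or self.labels
        n = len(labels)
        V = np.zeros((n, n))
        for i in range(n):
            pi = paths[labels[i]]
            V[i, i] = sum(l for _, l in pi)
            for j in range(i + 1, n):
                pj = paths[labels[j]]
                shared = 0.0
                for k in range(min(len(pi), len(pj))):
                    if pi[k][0] is pj[k][0]:
                        shared += pi[k][1]
                    else:
                        break
                V[i, j] = V[j, i] = shared
        return V


def neighbor_joining(dist: LabeledSymMatrix) -> PopulationTree:
    """Saitou–Nei neighbor joining with the canonical Q-matrix and branch
    lengths; ties broken on the lowest-index pair, negative branch lengths
    clamped to zero (and counted)."""
    D = dist.values.astype(float).copy()
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix not symmetric")
    if (D < -1e-12).any():
        raise ValueError("negative distances")
    labels = list(dist.labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    nodes: list[_Node] = [_Node(name=l) for l in labels]
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index (i, j) among minima, i < j
        qmin = Q.min()
        cand = np.argwhere(np.isclose(Q, qmin))
        i, j = min((min(a, b), max(a, b)) for a, b in cand)
        dij = D[i, j]
        li = clamp(0.5 * dij + (r[i] - r[j]) / (2.0 * (n - 2)))
        lj = clamp(dij - (0.5 * dij + (r[i] - r[j]) / (2.0 * (n - 2))))
        new = _Node(None, [(nodes[i], li), (nodes[j], lj)])
        dnew = 0.5 * (D[i] + D[j] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.zeros((n - 1, n - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
    # final three-taxon star: closed-form branch lengths
    a, b, c = 0, 1, 2
    la = clamp(0.5 * (D[a, b] + D[a, c] - D[b, c]))
    lb = clamp(0.5 * (D[a, b] + D[b, c] - D[a, c]))
    lc = clamp(0.5 * (D[a, c] + D[b, c] - D[a, b]))
    root = _Node(None, [(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return PopulationTree(root=root, labels=labels, clamped_branches=clamped)


def genetic_distance_for_tree(msat: MsatGenotypeTable) -> LabeledSymMatrix:
    """Population genetic distance for tree building: the Bhattacharyya
    complement 1 - sum_a sqrt(p1a * p2a), averaged over loci.  Bounded in
    [0, 1], 0 for identical frequency vectors, 1 for disjoint supports."""
    from .differentiation import msat_allele_frequencies

    per_locus = msat_allele_frequencies(msat)
    pops = msat.populations
    n = len(pops)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comps = []
            for df in per_locus.values():
                p1 = df.to_numpy()[i]
                p2 = df.to_numpy()[j]
                if np.isnan(p1).any() or np.isnan(p2).any():
                    continue
                comps.append(1.0 - np.sum(np.sqrt(p1 * p2)))
            vals[i, j] = vals[j, i] = float(np.mean(comps))
    return LabeledSymMatrix(pops, vals)


# ---------------------------------------------------------------------------
# PGLS with Pagel's lambda


@dataclass
class PglsResult:
    coefficients: pd.DataFrame  # coef, se, t, p per predictor
    lam: float
    log_likelihood: float
    aic: float
    sigma2: float
    flagged: bool = False


def _lambda_vcv(V: np.ndarray, lam: float) -> np.ndarray:
    """Pagel-lambda working covariance: the tree's Brownian covariance is
    first normalized to a correlation matrix (as in correlation-structure
    GLS), then off-diagonal correlations are scaled by lambda, so lambda=0
    is exactly OLS and lambda=1 the full tree structure."""
    d = np.sqrt(np.diag(V))
    C = V / np.outer(d, d)
    W = lam * C
    np.fill_diagonal(W, 1.0)
    return W


def _pd_bounds(V: np.ndarray, lo: float = -5.0, hi: float = 5.0) -> tuple[float, float]:
    """Widest [lambda_lo, lambda_hi] keeping V(lambda) positive definite."""

    def is_pd(lam: float) -> bool:
        try:
            np.linalg.cholesky(_lambda_vcv(V, lam))
            return True
        except np.linalg.LinAlgError:
            return False

    if not is_pd(0.0):
        raise ValueError("tree covariance degenerate even at lambda = 0")

    def bisect(target: float) -> float:
        if is_pd(target):
            return target
        a, b = 0.0, target  # is_pd(a), not is_pd(b)
        for _ in range(80):
            mid = (a + b) / 2
            if is_pd(mid):
                a = mid
            else:
                b = mid
        return a

    return bisect(lo), bisect(hi)


def _gls_loglik(y: np.ndarray, X: np.ndarray, W: np.ndarray):
    n = len(y)
    L = np.linalg.cholesky(W)
    Xi = np.linalg.solve(L, X)
    yi = np.linalg.solve(L, y)
    beta, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
    resid = yi - Xi @ beta
    sigma2 = float(resid @ resid) / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2) + logdet + n)
    return ll, beta, sigma2, Xi, yi


def fit_pgls(
    response: pd.Series,
    predictors: pd.DataFrame,
    tree: PopulationTree,
    lambda_mode: str = "ml",
    lambda_bounds: str = "constrained",
    grid_size: int = 101,
) -> PglsResult:
    """PGLS regression with Pagel's lambda estimated by profile ML.

    The Brownian covariance V comes from the tree; V(lambda) scales the
    off-diagonal (shared-history) entries.  ``lambda_bounds`` is
    "constrained" ([0, lambda_max] with lambda_max the positive-definite
    limit, capped at 1 when the PD limit exceeds it is NOT applied — the
    PD limit can exceed 1) or "unconstrained" (the full PD interval, which
    admits lambda > 1 or < 0).  ``lambda_mode`` "ml" profiles lambda; a
    float fixes it.
    """
    labels = list(response.index)
    if set(labels) != set(tree.labels):
        raise ValueError("tree leaves and observations differ")
    V = tree.vcv(labels)
    y = response.to_numpy(float)
    X = np.column_stack([np.ones(len(y)), predictors.loc[labels].to_numpy(float)])
    names = ["intercept"] + list(predictors.columns)

    lo_pd, hi_pd = _pd_bounds(V)
    if lambda_bounds == "constrained":
        lo, hi = 0.0, hi_pd
    elif lambda_bounds == "unconstrained":
        lo, hi = lo_pd, hi_pd
    else:
        raise ValueError(f"unknown lambda_bounds {lambda_bounds!r}")

    def nll(lam: float) -> float:
        try:
            ll, *_ = _gls_loglik(y, X, _lambda_vcv(V, lam))
        except np.linalg.LinAlgError:
            return np.inf
        return -ll

    flagged = False
    if isinstance(lambda_mode, (int, float)):
        lam = float(lambda_mode)
    else:
        grid = np.linspace(lo, hi * 0.999, grid_size)
        vals = np.array([nll(g) for g in grid])
        k = int(np.argmin(vals))
        a = grid[max(0, k - 1)]
        b = grid[min(grid_size - 1, k + 1)]
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(nll, bounds=(a, b), method="bounded")
        lam = float(res.x) if res.fun <= vals[k] else float(grid[k])
    try:
        W = _lambda_vcv(V, lam)
        ll, beta, sigma2, Xi, yi = _gls_loglik(y, X, W)
    except np.linalg.LinAlgError:
        flagged = True
        lam = 0.0
        W = _lambda_vcv(V, lam)
        ll, beta, sigma2, Xi, yi = _gls_loglik(y, X, W)
    n, p = X.shape
    XtX_inv = np.linalg.pinv(Xi.T @ Xi)
    dof = n - p
    s2_unbiased = sigma2 * n / dof if dof > 0 else np.nan
    se = np.sqrt(np.diag(XtX_inv) * s2_unbiased)
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    coef = pd.DataFrame(
        {"coef": beta, "se": se, "t": tvals, "p_value": pvals}, index=names
    )
    aic = -2 * ll + 2 * (p + 2)  # + sigma2 and lambda
    return PglsResult(coef, lam, float(ll), float(aic), float(sigma2), flagged)


def holm_bonferroni(p_values: pd.Series) -> pd.Series:
    """Holm step-down adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    adj = multipletests(p_values.to_numpy(float), method="holm")[1]
    return pd.Series(adj, index=p_values.index, name="p_holm")
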