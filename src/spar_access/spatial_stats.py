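"""Spatial statistics: weights matrices, Moran's I, OLS baseline, and the
maximum-likelihood spatial-lag model.

The lag model is y = rho * W y + X beta + eps with W a row-standardized
spatial weights matrix.  It is fit by maximizing the concentrated
log-likelihood over rho, with the log-determinant term
sum_i log(1 - rho * lambda_i) computed from the eigenvalues of W
(Ord's eigenvalue method); the likelihood-ratio test against OLS and AIC
quantify the gain from modelling spatial dependence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse, stats
from scipy.spatial import cKDTree

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "OlsFit",
    "SpatialLagFit",
    "build_knn_weights",
    "build_queen_weights",
    "correlation_filter",
    "morans_i",
    "fit_ols",
    "fit_spatial_lag",
]


@dataclass
class SpatialWeights:
    """Row-standardized spatial weights on n observations.

    ``neighbours[i]`` lists the neighbours of observation i (indices into
    0..n-1); ``weights[i]`` the matching row-standardized weights.  The
    neighbour structure is symmetric before row standardization; the
    diagonal is zero.
    """

    n: int
    neighbours: Dict[int, List[int]]
    weights: Dict[int, List[float]]

    def __post_init__(self) -> None:
        for i, nbrs in self.neighbours.items():
            if i in nbrs:
                raise ValueError(f"observation {i}: nonzero diagonal")
            row = self.weights.get(i, [])
            if len(row) != len(nbrs):
                raise ValueError(f"observation {i}: weight/neighbour mismatch")
            if nbrs and abs(sum(row) - 1.0) > 1e-12:
                raise ValueError(f"observation {i}: row not standardized")

    def to_sparse(self) -> sparse.csr_matrix:
        rows, cols, vals = [], [], []
        for i, nbrs in self.neighbours.items():
            for j, w in zip(nbrs, self.weights[i]):
                rows.append(i)
                cols.append(j)
                vals.append(w)
        return sparse.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

    def to_dense(self) -> np.ndarray:
        return self.to_sparse().toarray()

    @property
    def s0(self) -> float:
        return float(sum(sum(r) for r in self.weights.values()))


def _standardize(n: int, adjacency: Dict[int, set]) -> SpatialWeights:
    neighbours = {i: sorted(adjacency.get(i, ())) for i in range(n)}
    weights = {
        i: ([1.0 / len(nbrs)] * len(nbrs) if nbrs else [])
        for i, nbrs in neighbours.items()
    }
    return SpatialWeights(n=n, neighbours=neighbours, weights=weights)


def build_knn_weights(points: Sequence[Tuple[float, float]], k: int = 8) -> SpatialWeights:
    """k-nearest-neighbour weights, symmetrized by union, row-standardized.

    Distance ties (including duplicate coordinates) are broken by index
    order, so the result is deterministic.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n <= k:
        raise ValueError(f"need more than k={k} points, got {n}")
    tree = cKDTree(pts)
    # query k+1 (self included); resolve ties deterministically by index
    dists, idxs = tree.query(pts, k=min(n, k + 2))
    adjacency: Dict[int, set] = {i: set() for i in range(n)}
    for i in range(n):
        cand = [(float(d), int(j)) for d, j in zip(dists[i], idxs[i]) if j != i]
        cand.sort()
        for _, j in cand[:k]:
            adjacency[i].add(j)
            adjacency[j].add(i)  # symmetrize by union
    return _standardize(n, adjacency)


def build_queen_weights(polygons: Sequence) -> SpatialWeights:
    """Queen contiguity from shapely polygons (any shared boundary point)."""
    from shapely.strtree import STRtree

    n = len(polygons)
    tree = STRtree(list(polygons))
    adjacency: Dict[int, set] = {i: set() for i in range(n)}
    for i, poly in enumerate(polygons):
        for j in tree.query(poly):
            j = int(j)
            if j != i and poly.intersects(polygons[j]):
                adjacency[i].add(j)
                adjacency[j].add(i)
    return _standardize(n, adjacency)


def correlation_filter(X: pd.DataFrame, cutoff: float = 0.70) -> List[str]:
    """Greedy collinearity screen: scan columns in order, dropping any
    whose absolute Pearson correlation with an already-retained column is
    >= ``cutoff``."""
    if X.shape[1] < 2:
        raise ValueError("need at least two covariates")
    stds = X.std(ddof=0)
    if (stds == 0).any():
        bad = stds.index[stds == 0][0]
        raise ValueError(f"constant column {bad!r}: correlation undefined")
    corr = X.corr().abs()
    retained: List[str] = []
    for col in X.columns:
        if all(corr.loc[col, kept] < cutoff for kept in retained):
            retained.append(col)
    return retained


@dataclass
class MoranResult:
    i_value: float
    expected: float
    p_perm: float
    n_perm: int


def morans_i(y: Sequence[float], W: SpatialWeights, n_perm: int = 999,
             seed: Optional[int] = None) -> MoranResult:
    """Global Moran's I with a two-sided permutation test.

    I = (n / S0) * (z' W z) / (z' z) with z the centred values; the
    permutation p-value counts random relabellings whose |I - mean(I_perm)|
    is at least that of the observed statistic.
    """
    y = np.asarray(y, dtype=float)
    if y.size != W.n:
        raise ValueError("length of y must match W")
    if np.ptp(y) == 0:
        raise ValueError("Moran's I undefined for constant y")
    Ws = W.to_sparse()
    s0 = W.s0
    if s0 == 0:
        raise ValueError("weights matrix has no links")
    n = W.n

    def stat(vals: np.ndarray) -> float:
        z = vals - vals.mean()
        return float(n / s0 * (z @ (Ws @ z)) / (z @ z))

    i_obs = stat(y)
    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    for b in range(n_perm):
        perms[b] = stat(rng.permutation(y))
    center = perms.mean()
    extreme = np.abs(perms - center) >= abs(i_obs - center) - 1e-15
    p = (1.0 + extreme.sum()) / (n_perm + 1.0)
    return MoranResult(i_value=i_obs, expected=-1.0 / (n - 1),
                       p_perm=float(p), n_perm=n_perm)


@dataclass
class OlsFit:
    coefficients: pd.Series
    std_errors: pd.Series
    residuals: np.ndarray
    log_likelihood: float
    r_squared: float


def _design(X: pd.DataFrame) -> Tuple[np.ndarray, List[str]]:
    names = ["Intercept"] + list(X.columns)
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    return mat, names


def fit_ols(y: Sequence[float], X: pd.DataFrame) -> OlsFit:
    """Ordinary least squares with intercept (Gaussian log-likelihood)."""
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    mat, names = _design(X)
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise ValueError("design matrix is rank deficient")
    res = sm.OLS(y, mat).fit()
    return OlsFit(
        coefficients=pd.Series(res.params, index=names),
        std_errors=pd.Series(res.bse, index=names),
        residuals=np.asarray(res.resid),
        log_likelihood=float(res.llf),
        r_squared=float(res.rsquared),
    )


@dataclass
class SpatialLagFit:
    rho: float
    coefficients: pd.Series
    std_errors: pd.Series
    z_values: pd.Series
    p_values: pd.Series
    rho_std_error: float
    sigma2: float
    log_likelihood: float
    lr_stat: float
    lr_p: float
    aic: float
    residuals: np.ndarray


def fit_spatial_lag(y: Sequence[float], X: pd.DataFrame,
                    W: SpatialWeights) -> SpatialLagFit:
    """Maximum-likelihood spatial-lag model y = rho*Wy + X*beta + eps.

    The concentrated log-likelihood in rho is maximized by bounded scalar
    search over (1/lambda_min, 1/lambda_max) of W's eigenvalues; the
    log-Jacobian uses Ord's eigenvalue expression.  Reported are beta and
    rho with asymptotic standard errors from the analytic information
    matrix, the likelihood-ratio test against OLS (1 df) and
    AIC = -2 logLik + 2k with k = #beta + 2 (rho and the error variance).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n != W.n:
        raise ValueError("length of y must match W")
    mat, names = _design(X)
    p = mat.shape[1]
    if n <= p:
        raise ValueError("need n > number of parameters")
    ols = fit_ols(y, X)

    Wd = W.to_dense()
    Wy = Wd @ y

    if W.s0 == 0:
        # no links: the lag term vanishes and the model is exactly OLS
        k = p + 2
        coef = ols.coefficients
        return SpatialLagFit(
            rho=0.0, coefficients=coef, std_errors=ols.std_errors,
            z_values=coef / ols.std_errors,
            p_values=pd.Series(2 * stats.norm.sf(np.abs(coef / ols.std_errors)),
                               index=names),
            rho_std_error=float("nan"),
            sigma2=float(ols.residuals @ ols.residuals / n),
            log_likelihood=ols.log_likelihood, lr_stat=0.0, lr_p=1.0,
            aic=-2 * ols.log_likelihood + 2 * k, residuals=ols.residuals,
        )

    lam = linalg.eigvals(Wd)
    if np.max(np.abs(lam.imag)) > 1e-8:
        raise ValueError("weights matrix has complex eigenvalues; use a "
                         "symmetric neighbour structure")
    lam = np.sort(lam.real)
    lam_min, lam_max = lam[0], lam[-1]
    lo = 1.0 / lam_min + 1e-8 if lam_min < 0 else -0.999999
    hi = 1.0 / lam_max - 1e-8 if lam_max > 0 else 0.999999

    # concentrated likelihood pieces: residuals of y and Wy on X
    XtX_inv = np.linalg.inv(mat.T @ mat)
    b0 = XtX_inv @ (mat.T @ y)
    bL = XtX_inv @ (mat.T @ Wy)
    e0 = y - mat @ b0
    eL = Wy - mat @ bL

    def neg_conc_ll(rho: float) -> float:
        e = e0 - rho * eL
        sig2 = (e @ e) / n
        logdet = np.sum(np.log(1.0 - rho * lam))
        return -(-0.5 * n * (np.log(2 * np.pi) + 1.0)
                 + logdet - 0.5 * n * np.log(sig2))

    opt = optimize.minimize_scalar(neg_conc_ll, bounds=(lo, hi),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    if not opt.success:
        raise RuntimeError(f"spatial-lag optimization failed: {opt.message}")
    rho = float(opt.x)
    llf = -float(opt.fun)

    beta = b0 - rho * bL
    resid = (y - rho * Wy) - mat @ beta
    sigma2 = float(resid @ resid / n)

    # asymptotic information matrix for (beta, rho, sigma2) [Anselin 1988]
    A_inv = np.linalg.inv(np.eye(n) - rho * Wd)
    WA = Wd @ A_inv
    WAXb = WA @ (mat @ beta)
    I_bb = mat.T @ mat / sigma2
    I_br = (mat.T @ WAXb / sigma2).reshape(-1, 1)
    tr_WA = np.trace(WA)
    I_rr = np.trace(WA @ WA) + np.trace(WA.T @ WA) + (WAXb @ WAXb) / sigma2
    I_rs = tr_WA / sigma2
    I_ss = n / (2 * sigma2 ** 2)
    dim = p + 2
    info = np.zeros((dim, dim))
    info[:p, :p] = I_bb
    info[:p, p] = I_br[:, 0]
    info[p, :p] = I_br[:, 0]
    info[p, p] = I_rr
    info[p, p + 1] = info[p + 1, p] = I_rs
    info[p + 1, p + 1] = I_ss
    cov = np.linalg.inv(info)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    beta_se, rho_se = se[:p], se[p]

    z = beta / beta_se
    pvals = 2 * stats.norm.sf(np.abs(z))
    lr = max(0.0, 2.0 * (llf - ols.log_likelihood))
    lr_p = float(stats.chi2.sf(lr, df=1))
    k = p + 2
    return SpatialLagFit(
        rho=rho,
        coefficients=pd.Series(beta, index=names),
        std_errors=pd.Series(beta_se, index=names),
        z_values=pd.Series(z, index=names),
        p_values=pd.Series(pvals, index=names),
        rho_std_error=float(rho_se),
        sigma2=sigma2,
        log_likelihood=llf,
        lr_stat=lr,
        lr_p=lr_p,
        aic=-2 * llf + 2 * k,
        residuals=resid,
    )
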