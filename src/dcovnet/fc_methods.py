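"""Functional-connectivity estimators.

Seven estimators over node-by-time matrices ``z``:

* ``cov`` — sample covariance (symmetric);
* ``pcov`` — precision matrix, the (pseudo-)inverse of the covariance;
* ``l1reg`` / ``l2reg`` — graphical-lasso and ridge-regularised precision;
* ``cgranger`` — conditional Granger causality with chi-square p-values;
* ``dcov_c`` — differential covariance ``cov(dz_i, z_j)``, directed;
* ``dcov_p`` — partial differential covariance, conditioning each ordered
  pair on all remaining nodes;
* ``dcov_s`` — sparse component of a sparse + low-rank split of ``dcov_p``.

Directed estimators use the sink-row orientation: entry ``(i, j)`` measures
the influence of source ``j`` on sink ``i`` (the derivative is taken on the
sink's trace).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import chi2

from .containers import (
    ConnectivityMatrix,
    IllConditionedError,
    SparseLatentConfig,
    TimeSeriesMatrix,
)
from .hemodynamics import numerical_derivative

__all__ = [
    "sample_covariance",
    "partial_covariance",
    "regularized_partial_covariance",
    "differential_covariance",
    "partial_differential_covariance",
    "sparse_latent_split",
    "conditional_granger",
]

#: ridge jitter applied to near-singular conditioning blocks, as a fraction
#: of the mean covariance diagonal
_RIDGE_FRACTION = 1e-8


def _standardize(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - values.mean(axis=1, keepdims=True)) / sd


def sample_covariance(z: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Unbiased sample covariance (divisor T - 1)."""
    c = np.cov(z.values, ddof=1)
    c = np.atleast_2d(c)
    return ConnectivityMatrix(c, list(z.labels), "cov", directed=False)


def partial_covariance(z: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Precision matrix: inverse (Moore-Penrose when rank-deficient) of the
    covariance.  Warns when the pseudo-inverse path is taken."""
    c = np.atleast_2d(np.cov(z.values, ddof=1))
    rank = np.linalg.matrix_rank(c)
    if rank < c.shape[0]:
        warnings.warn(
            f"covariance is rank-deficient (rank {rank} < {c.shape[0]}); "
            "using the Moore-Penrose pseudo-inverse",
            RuntimeWarning,
        )
        p = np.linalg.pinv(c, hermitian=True)
    else:
        p = np.linalg.inv(c)
    p = 0.5 * (p + p.T)
    return ConnectivityMatrix(p, list(z.labels), "pcov", directed=False)


def regularized_partial_covariance(
    z: TimeSeriesMatrix,
    kind: str = "L1",
    penalty: float | None = None,
) -> ConnectivityMatrix:
    """L1 (graphical-lasso) or L2 (ridge) regularised precision matrix.

    Default penalties follow common practice for these regularisers:
    ``lambda = 10`` for L1 and ``rho = 0.1`` for L2.  The L1 penalty is
    applied on the per-sample likelihood scale (graphical-lasso
    regularisation ``lambda / T``); the L2 estimator inverts
    ``Cov + rho * mean(diag(Cov)) * I``.
    """
    kind = kind.upper()
    if kind not in ("L1", "L2"):
        raise ValueError("kind must be 'L1' or 'L2'")
    if penalty is None:
        penalty = 10.0 if kind == "L1" else 0.1
    if penalty < 0:
        raise ValueError("penalty must be nonnegative")
    if penalty == 0:
        out = partial_covariance(z)
        return ConnectivityMatrix(out.values, list(z.labels),
                                  "l1reg" if kind == "L1" else "l2reg", directed=False)
    c = np.atleast_2d(np.cov(z.values, ddof=1))
    if kind == "L2":
        p = np.linalg.inv(c + penalty * np.mean(np.diag(c)) * np.eye(c.shape[0]))
        p = 0.5 * (p + p.T)
        return ConnectivityMatrix(p, list(z.labels), "l2reg", directed=False)
    from sklearn.covariance import graphical_lasso

    alpha = penalty / z.n_samples
    meta: dict = {"alpha": alpha}
    try:
        _, p = graphical_lasso(c, alpha=alpha, max_iter=200)
    except Exception as exc:  # non-convergence reported, not swallowed
        raise RuntimeError(f"graphical lasso failed to converge: {exc}") from exc
    p = 0.5 * (p + p.T)
    return ConnectivityMatrix(p, list(z.labels), "l1reg", directed=False, meta=meta)


def _dz_and_z(z: TimeSeriesMatrix) -> tuple[np.ndarray, np.ndarray]:
    """First derivative and the signal trimmed to the same support."""
    dz = numerical_derivative(z, 1).values
    zz = z.values[:, 1:-1]
    return dz, zz


def _cross_cov(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """cov(a_i, b_j) with divisor T - 1, rows are variables."""
    T = a.shape[1]
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    return ac @ bc.T / (T - 1)


def differential_covariance(z: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Differential covariance ``dcov_c[i, j] = cov(dz_i, z_j)``.

    The derivative is a central difference; the signal is trimmed to the
    derivative's support.  For stationary data the result is antisymmetric
    up to sampling error; the ratio ``||C + C^T||_F / ||C||_F`` is recorded
    in ``meta['antisymmetry_ratio']``.
    """
    if z.n_samples < 5:
        raise ValueError("need T >= 5 samples")
    dz, zz = _dz_and_z(z)
    c = _cross_cov(dz, zz)
    norm = np.linalg.norm(c)
    ratio = float(np.linalg.norm(c + c.T) / norm) if norm > 0 else 0.0
    return ConnectivityMatrix(c, list(z.labels), "dcov_c", directed=True,
                              meta={"antisymmetry_ratio": ratio})


def _solve_conditioning(cov_KK: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve ``cov_KK x = rhs``, adding ridge jitter if near-singular."""
    if cov_KK.size == 0:
        return rhs
    try:
        cond = np.linalg.cond(cov_KK)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError
        return np.linalg.solve(cov_KK, rhs)
    except np.linalg.LinAlgError:
        jitter = _RIDGE_FRACTION * float(np.mean(np.diag(cov_KK)))
        return np.linalg.solve(cov_KK + jitter * np.eye(cov_KK.shape[0]), rhs)


def partial_differential_covariance(
    z: TimeSeriesMatrix,
    standardize: bool = False,
) -> ConnectivityMatrix:
    """Partial differential covariance.

    For each ordered pair ``(i, j)``,

        dcov_p[i, j] = dcov_c[i, j] - Cov_jK Cov_KK^-1 dcov_c[i, K]^T

    where ``K`` is the set of all nodes other than ``i`` and ``j`` — the
    covariance of the pair's traces after regressing out every other node.
    With two nodes the conditioning set is empty and the result equals the
    differential covariance.  Diagonal entries condition on all other nodes.
    """
    if z.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    work = z if not standardize else z.with_values(_standardize(z.values))
    dz, zz = _dz_and_z(work)
    n = work.n_nodes
    dc = _cross_cov(dz, zz)
    cov = np.atleast_2d(np.cov(zz, ddof=1))
    out = dc.copy()
    idx = np.arange(n)
    for i in range(n):
        for j in range(n):
            K = idx[(idx != i) & (idx != j)]
            if K.size == 0:
                continue
            beta = _solve_conditioning(cov[np.ix_(K, K)], cov[K, j])
            out[i, j] = dc[i, j] - dc[i, K] @ beta
    return ConnectivityMatrix(out, list(z.labels), "dcov_p", directed=True,
                              meta={"standardized": standardize})


def _svd_shrink(M: np.ndarray, thresh: float) -> np.ndarray:
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    s = np.maximum(s - thresh, 0.0)
    return (U * s) @ Vt


def _soft_threshold(M: np.ndarray, thresh: float) -> np.ndarray:
    return np.sign(M) * np.maximum(np.abs(M) - thresh, 0.0)


def sparse_latent_split(
    dp: ConnectivityMatrix,
    cfg: SparseLatentConfig | None = None,
) -> tuple[ConnectivityMatrix, ConnectivityMatrix]:
    """Split the partial dCov into sparse couplings and a low-rank remainder.

    Solves ``min  alpha * ||S||_1 + ||L||_*  s.t.  S + L = dp`` by inexact
    augmented-Lagrange multipliers (singular-value shrinkage for ``L``,
    soft-thresholding for ``S``).  The sparse part keeps direct couplings
    between observed nodes; the low-rank part absorbs shared fluctuations
    from unobserved common inputs.  The nuclear norm is used as the
    low-rank penalty (it reduces to the trace on positive-semidefinite
    arguments, and the partial dCov is not symmetric).

    Returns ``(sparse, low_rank)``; convergence diagnostics are stored in
    ``sparse.meta``.
    """
    cfg = cfg or SparseLatentConfig()
    M = dp.values
    n = M.shape[0]
    alpha = cfg.resolve_alpha(n)
    norm_M = np.linalg.norm(M)
    if norm_M == 0:
        zero = np.zeros_like(M)
        s_cm = ConnectivityMatrix(zero, list(dp.labels), "dcov_s", dp.directed,
                                  meta={"converged": True, "n_iter": 0, "residual": 0.0,
                                        "alpha_penalty": alpha})
        l_cm = ConnectivityMatrix(zero.copy(), list(dp.labels), "dcov_latent", dp.directed)
        return s_cm, l_cm

    two_norm = np.linalg.norm(M, 2)
    mu = 1.25 / two_norm
    mu_bar = mu * 1e7
    rho = 1.5
    Y = M / max(two_norm, np.max(np.abs(M)) / alpha)
    S = np.zeros_like(M)
    L = np.zeros_like(M)
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        L = _svd_shrink(M - S + Y / mu, 1.0 / mu)
        S = _soft_threshold(M - L + Y / mu, alpha / mu)
        resid = M - L - S
        Y = Y + mu * resid
        mu = min(mu * rho, mu_bar)
        rel = np.linalg.norm(resid) / norm_M
        if rel < cfg.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"sparse-latent split did not reach tol={cfg.tol:g} in "
            f"{cfg.max_iter} iterations (residual {rel:.2e}); returning best iterate",
            RuntimeWarning,
        )
    meta = {"converged": converged, "n_iter": it,
            "residual": float(np.linalg.norm(M - L - S)), "alpha_penalty": alpha}
    s_cm = ConnectivityMatrix(S, list(dp.labels), "dcov_s", dp.directed, meta=meta)
    l_cm = ConnectivityMatrix(L, list(dp.labels), "dcov_latent", dp.directed)
    return s_cm, l_cm


def _lag_design(x: np.ndarray, order: int, start: int, keep: np.ndarray | None = None) -> np.ndarray:
    """Design matrix [1, lagged values] for a VAR regression.

    Rows are time points ``start .. T-1``; columns are an intercept followed
    by ``order`` lags of each kept node.
    """
    n, T = x.shape
    nodes = np.arange(n) if keep is None else keep
    cols = [np.ones(T - start)]
    for lag in range(1, order + 1):
        for node in nodes:
            cols.append(x[node, start - lag : T - lag])
    return np.column_stack(cols)


def _residual_ss(design: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each target column regressed on design."""
    coef, _, _, _ = np.linalg.lstsq(design, targets, rcond=None)
    resid = targets - design @ coef
    return np.sum(resid ** 2, axis=0)


def conditional_granger(
    z: TimeSeriesMatrix,
    max_order: int = 10,
) -> tuple[ConnectivityMatrix, np.ndarray]:
    """Conditional Granger causality with asymptotic chi-square p-values.

    The VAR order is selected by the Akaike information criterion over
    ``1..max_order`` (ties resolved toward the smaller order, all candidates
    scored on a common sample).  ``F[i, j]`` is the log-ratio of the
    residual variance of sink ``i`` when source ``j``'s lags are excluded
    versus included, conditioning on all remaining nodes; the sample-scaled
    statistic is referred to a chi-square law with the selected order as
    degrees of freedom.  Diagonal entries are 0 with p = 1; p-values are
    not corrected for multiple comparisons.
    """
    x = z.values
    n, T = x.shape
    if T <= 3 * n * max_order:
        raise ValueError("time series too short for this node count and max order")

    # order selection on the common sample t >= max_order
    aics = []
    for q in range(1, max_order + 1):
        design = _lag_design(x, q, max_order)
        cond = np.linalg.cond(design)
        if cond > 1e10:
            raise IllConditionedError(
                f"VAR design at order {q} has condition number {cond:.3g}"
            )
        targets = x[:, max_order:].T
        rss = _residual_ss(design, targets)
        t_eff = targets.shape[0]
        # Gaussian log-likelihood with diagonal residual covariance is enough
        # for ranking; 2k penalty per scalar parameter
        aic = t_eff * np.sum(np.log(rss / t_eff)) + 2.0 * (n * q + 1) * n
        aics.append(aic)
    order = int(np.argmin(aics)) + 1

    design_full = _lag_design(x, order, order)
    cond = np.linalg.cond(design_full)
    if cond > 1e10:
        raise IllConditionedError(f"VAR design has condition number {cond:.3g}")
    targets = x[:, order:].T
    t_eff = targets.shape[0]
    rss_full = _residual_ss(design_full, targets)

    F = np.zeros((n, n))
    pvals = np.ones((n, n))
    idx = np.arange(n)
    for j in range(n):
        keep = idx[idx != j]
        design_red = _lag_design(x, order, order, keep=keep)
        rss_red = _residual_ss(design_red, targets)
        for i in range(n):
            if i == j:
                continue
            f = max(0.0, float(np.log(rss_red[i] / rss_full[i])))
            F[i, j] = f
            pvals[i, j] = float(chi2.sf(t_eff * f, df=order))
    cm = ConnectivityMatrix(F, list(z.labels), "cgranger", directed=True,
                            meta={"order": order, "df": order, "t_eff": t_eff})
    return cm, pvals
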