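"""Classical and ridge-regularized canonical correlation analysis.

Classical CCA maximizes cor(Xa, Yb) subject to var(Xa) = var(Yb) = 1; the
solutions come from the SVD of the whitened cross-covariance
C_XX^{-1/2} C_XY C_YY^{-1/2}.  When variables outnumber samples the block
covariances are singular; ridge CCA (rCCA) replaces them by C_XX + l1*I and
C_YY + l2*I.  Because the fits run on standardized data, the sample
covariance (ddof=1) equals the correlation matrix, so regularizing the
covariance and the correlation coincide.

For rCCA the reported canonical correlations ``rho`` are the singular
values of the ridge-whitened cross-covariance — the quantity the ridge
eigenproblem actually maximizes and the conventional "canonical values" of
regularized CCA software.  They are shrunk below the empirical correlation
of the returned variates, which remains available through
``ProjectionFit.variate_correlations()``.  With l1 = l2 = 0 the two
definitions coincide and rCCA reduces exactly to classical CCA.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cholesky, solve_triangular, svd, LinAlgError

from .dataset import PairedDataset
from .pls import ProjectionFit

__all__ = ["fit_cca", "fit_rcca", "tune_rcca", "default_lambda_grid"]


def _covariances(data: PairedDataset):
    n = data.n
    cxx = data.x.T @ data.x / (n - 1)
    cyy = data.y.T @ data.y / (n - 1)
    cxy = data.x.T @ data.y / (n - 1)
    return cxx, cyy, cxy


def _whitened_solution(data, n_dim, lam1, lam2):
    cxx, cyy, cxy = _covariances(data)
    cxx = cxx + lam1 * np.eye(data.p)
    cyy = cyy + lam2 * np.eye(data.q)
    try:
        lx = cholesky(cxx, lower=True)
        ly = cholesky(cyy, lower=True)
    except LinAlgError as err:
        raise ValueError(
            "singular block covariance matrix; use fit_rcca with positive "
            "regularization parameters"
        ) from err
    # K = Lx^{-1} Cxy Ly^{-T}
    k = solve_triangular(lx, cxy, lower=True)
    k = solve_triangular(ly, k.T, lower=True).T
    uw, s, vwt = svd(k, full_matrices=False)
    a = solve_triangular(lx.T, uw[:, :n_dim], lower=False)
    b = solve_triangular(ly.T, vwt[:n_dim].T, lower=False)
    return a, b, s[:n_dim]


def _finish_fit(data, a, b, s, method, lam1=None, lam2=None):
    n_dim = a.shape[1]
    u = data.x @ a
    v = data.y @ b
    # scale variates to unit variance (var(Xa) = var(Yb) = 1)
    su = u.std(axis=0, ddof=1)
    sv = v.std(axis=0, ddof=1)
    a, u = a / su, u / su
    b, v = b / sv, v / sv
    # sign convention: largest-magnitude X loading positive per dimension
    for l in range(n_dim):
        j = np.argmax(np.abs(a[:, l]))
        if a[j, l] < 0:
            a[:, l] *= -1
            u[:, l] *= -1
            b[:, l] *= -1
            v[:, l] *= -1
    phi = data.x.T @ u / (data.n - 1)  # = cor(X^j, U_l): regression on unit-variance U
    psi = data.y.T @ v / (data.n - 1)
    return ProjectionFit(
        method=method,
        n_dim=n_dim,
        a=a,
        b=b,
        u=u,
        v=v,
        rho=np.asarray(s, dtype=float),
        phi=phi,
        psi=psi,
        u_sd=u.std(axis=0, ddof=1),
        v_sd=v.std(axis=0, ddof=1),
        x_ids=data.x_ids,
        y_ids=data.y_ids,
        lambda1=lam1,
        lambda2=lam2,
    )


def fit_cca(data: PairedDataset, n_dim: int) -> ProjectionFit:
    """Classical CCA; requires invertible block covariances (roughly
    n > p + q).  Raises ValueError pointing at :func:`fit_rcca` when a
    block covariance is singular."""
    if not data.standardized:
        raise ValueError("fit requires standardized data; call .standardize() first")
    if not 1 <= n_dim <= min(data.p, data.q):
        raise ValueError(f"n_dim must be in [1, {min(data.p, data.q)}]")
    a, b, s = _whitened_solution(data, n_dim, 0.0, 0.0)
    # without regularization the singular values ARE cor(U_l, V_l)
    return _finish_fit(data, a, b, s, "cca")


def fit_rcca(
    data: PairedDataset, n_dim: int, lambda1: float, lambda2: float
) -> ProjectionFit:
    """Ridge CCA with covariances C_XX + lambda1*I and C_YY + lambda2*I;
    works when p, q > n."""
    if not data.standardized:
        raise ValueError("fit requires standardized data; call .standardize() first")
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("regularization parameters must be nonnegative")
    if not 1 <= n_dim <= min(data.p, data.q):
        raise ValueError(f"n_dim must be in [1, {min(data.p, data.q)}]")
    a, b, s = _whitened_solution(data, n_dim, lambda1, lambda2)
    return _finish_fit(data, a, b, s, "rcca", lambda1, lambda2)


def default_lambda_grid() -> np.ndarray:
    """11 logarithmically spaced ridge values in [1e-3, 1]."""
    return np.logspace(-3, 0, 11)


def tune_rcca(
    data: PairedDataset,
    lambda_grid=None,
    n_folds: int = 5,
    seed: int = 42,
) -> tuple[float, float]:
    """Choose (lambda1, lambda2) by k-fold cross-validation maximizing the
    mean held-out correlation of the first canonical variate pair.

    Every pair from the grid's Cartesian product is evaluated; folds are
    assigned deterministically from ``seed``.  Ties keep the first pair in
    grid order.
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    lambda_grid = [float(l) for l in lambda_grid]
    if not lambda_grid:
        raise ValueError("lambda grid must be nonempty")
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    n = data.n
    if n < 2 * n_folds:
        raise ValueError(f"too few samples ({n}) for {n_folds}-fold CV")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    best = None
    for l1 in lambda_grid:
        for l2 in lambda_grid:
            scores = []
            for test_idx in folds:
                train_idx = np.setdiff1d(perm, test_idx)
                train = PairedDataset(
                    data.x[train_idx], data.y[train_idx],
                    x_ids=data.x_ids, y_ids=data.y_ids,
                ).standardize()
                a, b, _ = _whitened_solution(train, 1, l1, l2)
                u = data.x[test_idx] @ a[:, 0]
                v = data.y[test_idx] @ b[:, 0]
                if u.std() == 0 or v.std() == 0:
                    scores.append(0.0)
                else:
                    scores.append(float(np.corrcoef(u, v)[0, 1]))
            mean_score = float(np.mean(scores))
            if best is None or mean_score > best[0]:
                best = (mean_score, l1, l2)
    return best[1], best[2]
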