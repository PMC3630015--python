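"""Partial Least Squares in regression and canonical mode, and sparse PLS.

PLS searches for unit-norm loading vectors a, b maximizing the covariance
cov(Xa, Yb); successive dimensions operate on deflated matrices.  Two
deflation schemes are supported:

* ``reg`` (regression mode, asymmetric, X predicts Y): both X and Y are
  deflated on the X-variate U.
* ``can`` (canonical mode, symmetric): X is deflated on U and Y on its own
  variate V.

Sparse PLS replaces the lasso penalty level by the number of variables to
keep: inside each power iteration the unnormalized loading is
soft-thresholded so that exactly ``keepX[l]`` (resp. ``keepY[l]``) entries
stay nonzero, then renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import PairedDataset

__all__ = ["ProjectionFit", "fit_pls", "fit_spls"]

MAX_ITER = 500
TOL = 1e-9

PLS_METHODS = {"pls-reg", "pls-can", "spls-reg", "spls-can"}
CCA_METHODS = {"cca", "rcca"}


@dataclass(frozen=True)
class ProjectionFit:
    """Result of any of the six projection fits.

    Attributes
    ----------
    method : one of cca, rcca, pls-reg, pls-can, spls-reg, spls-can
    a, b : (p, d) and (q, d) loading matrices.
    u, v : (n, d) variates U = X a and V = Y b (on deflated matrices for
        the PLS family).
    rho : per-dimension association: cor(U_l, V_l) for PLS and classical
        CCA; for rCCA the regularized canonical correlations (the singular
        values of the ridge-whitened cross-covariance), which is what the
        field reports as "canonical values".
    phi, psi : per-dimension regression coefficients of X on U and of Y on
        U (reg mode) or V (can mode / CCA).
    u_sd, v_sd : standard deviations (ddof=1) of the U and V columns.
    keep_x, keep_y : per-dimension selection counts (sparse family only).
    lambda1, lambda2 : ridge parameters (rCCA only).
    y_residual_norms : Frobenius norm of the deflated Y after each
        dimension (PLS family).
    """

    method: str
    n_dim: int
    a: np.ndarray
    b: np.ndarray
    u: np.ndarray
    v: np.ndarray
    rho: np.ndarray
    phi: np.ndarray
    psi: np.ndarray
    u_sd: np.ndarray
    v_sd: np.ndarray
    x_ids: list[str]
    y_ids: list[str]
    keep_x: tuple[int, ...] | None = None
    keep_y: tuple[int, ...] | None = None
    lambda1: float | None = None
    lambda2: float | None = None
    y_residual_norms: np.ndarray | None = None

    @property
    def mode(self) -> str:
        """Deflation mode: 'reg', 'can', or 'cca' for the CCA family."""
        if self.method in CCA_METHODS:
            return "cca"
        return self.method.split("-")[1]

    @property
    def is_sparse(self) -> bool:
        return self.method.startswith("spls")

    def variate_correlations(self) -> np.ndarray:
        """Empirical cor(U_l, V_l) of the returned variates."""
        out = np.empty(self.n_dim)
        for l in range(self.n_dim):
            out[l] = np.corrcoef(self.u[:, l], self.v[:, l])[0, 1]
        return out

    def selected_x(self, dim: int | None = None) -> list[str]:
        """Ids of X variables with a nonzero loading on ``dim`` (1-based),
        or on any dimension when dim is None."""
        nz = (self.a != 0).any(axis=1) if dim is None else self.a[:, dim - 1] != 0
        return [i for i, keep in zip(self.x_ids, nz) if keep]

    def selected_y(self, dim: int | None = None) -> list[str]:
        nz = (self.b != 0).any(axis=1) if dim is None else self.b[:, dim - 1] != 0
        return [i for i, keep in zip(self.y_ids, nz) if keep]


def _soft_threshold_keep(z: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold z so exactly ``keep`` entries remain nonzero.

    The threshold is the midpoint between the keep-th and (keep+1)-th
    largest absolute values; ties are broken by variable index order.
    """
    m = z.size
    if keep >= m:
        return z.copy()
    abs_z = np.abs(z)
    # stable order: by descending magnitude, then ascending index
    order = np.lexsort((np.arange(m), -abs_z))
    kth, next_ = abs_z[order[keep - 1]], abs_z[order[keep]]
    thr = 0.5 * (kth + next_)
    out = np.sign(z) * np.maximum(abs_z - thr, 0.0)
    # exact tie between kth and (keep+1)-th magnitude: enforce the count
    # by zeroing everything beyond the first ``keep`` in the stable order
    nz = np.zeros(m, dtype=bool)
    nz[order[:keep]] = True
    out[~nz] = 0.0
    if np.count_nonzero(out) < keep:
        # threshold collapsed some kept entries exactly to zero (all-tied
        # magnitudes); fall back to hard selection of the raw values
        out = np.where(nz, z, 0.0)
    return out


def _fix_sign(a, b, u, v):
    """Make the largest-magnitude entry of a positive; flip the whole
    dimension consistently so cor(u, v) is unchanged."""
    j = np.argmax(np.abs(a))
    if a[j] < 0:
        return -a, -b, -u, -v
    return a, b, u, v


def _nipals_dimension(x, y, keep_x=None, keep_y=None):
    """One PLS dimension by alternating power iteration (NIPALS)."""
    # deterministic start at the dense covariance maximizer: the leading
    # right singular vector of X'Y (for sparse fits this also selects the
    # dominant basin rather than an arbitrary one)
    _, _, vt = np.linalg.svd(x.T @ y, full_matrices=False)
    v = y @ vt[0]
    if not v.any():
        v = y[:, 0] + 1.0  # degenerate zero cross-covariance; any start works
    a_old = None
    for _ in range(MAX_ITER):
        a = x.T @ v
        if keep_x is not None:
            a = _soft_threshold_keep(a, keep_x)
        na = np.linalg.norm(a)
        if na == 0:
            raise ValueError("X block is exhausted (zero loading); reduce n_dim")
        a /= na
        u = x @ a
        b = y.T @ u
        if keep_y is not None:
            b = _soft_threshold_keep(b, keep_y)
        nb = np.linalg.norm(b)
        if nb == 0:
            raise ValueError("Y block is exhausted (zero loading); reduce n_dim")
        b /= nb
        v = y @ b
        if a_old is not None and np.abs(a - a_old).max() < TOL:
            break
        a_old = a
    else:
        raise RuntimeError(f"NIPALS did not converge in {MAX_ITER} iterations")
    return _fix_sign(a, b, u, v)


def _fit_pls_family(data, n_dim, mode, method, keep_x=None, keep_y=None):
    if not data.standardized:
        raise ValueError("fit requires standardized data; call .standardize() first")
    if mode not in ("reg", "can"):
        raise ValueError(f"mode must be 'reg' or 'can', got {mode!r}")
    n, p, q = data.n, data.p, data.q
    limit = p if mode == "reg" else min(p, q)
    if not 1 <= n_dim <= limit:
        raise ValueError(f"n_dim must be in [1, {limit}] for mode {mode!r}")
    x = data.x.copy()
    y = data.y.copy()
    A = np.zeros((p, n_dim))
    B = np.zeros((q, n_dim))
    U = np.zeros((n, n_dim))
    V = np.zeros((n, n_dim))
    Phi = np.zeros((p, n_dim))
    Psi = np.zeros((q, n_dim))
    rho = np.zeros(n_dim)
    resid = np.zeros(n_dim)
    for l in range(n_dim):
        if np.linalg.norm(x) < 1e-12:
            raise ValueError(f"X rank exhausted after {l} dimensions")
        kx = keep_x[l] if keep_x is not None else None
        ky = keep_y[l] if keep_y is not None else None
        a, b, u, v = _nipals_dimension(x, y, kx, ky)
        rho[l] = np.corrcoef(u, v)[0, 1]
        phi = x.T @ u / (u @ u)
        x = x - np.outer(u, phi)
        if mode == "reg":
            psi = y.T @ u / (u @ u)
            y = y - np.outer(u, psi)
        else:
            psi = y.T @ v / (v @ v)
            y = y - np.outer(v, psi)
        A[:, l], B[:, l], U[:, l], V[:, l] = a, b, u, v
        Phi[:, l], Psi[:, l] = phi, psi
        resid[l] = np.linalg.norm(y)
    return ProjectionFit(
        method=method,
        n_dim=n_dim,
        a=A,
        b=B,
        u=U,
        v=V,
        rho=rho,
        phi=Phi,
        psi=Psi,
        u_sd=U.std(axis=0, ddof=1),
        v_sd=V.std(axis=0, ddof=1),
        x_ids=data.x_ids,
        y_ids=data.y_ids,
        keep_x=tuple(keep_x) if keep_x is not None else None,
        keep_y=tuple(keep_y) if keep_y is not None else None,
        y_residual_norms=resid,
    )


def fit_pls(data: PairedDataset, n_dim: int, mode: str = "can") -> ProjectionFit:
    """Fit ordinary PLS with ``n_dim`` dimensions.

    Parameters
    ----------
    data
        Standardized :class:`PairedDataset`.
    mode
        'reg' for regression mode (X predicts Y; both blocks deflated on
        U) or 'can' for canonical mode (symmetric; Y deflated on V).
    """
    return _fit_pls_family(data, n_dim, mode, f"pls-{mode}")


def _norm_keep(keep, n_dim, limit, what):
    if keep is None:
        return [limit] * n_dim
    if np.isscalar(keep):
        keep = [int(keep)] * n_dim
    keep = [int(k) for k in keep]
    if len(keep) != n_dim:
        raise ValueError(f"{what} must give one count per dimension ({n_dim})")
    if any(not 1 <= k <= limit for k in keep):
        raise ValueError(f"every {what} count must lie in [1, {limit}]")
    return keep


def fit_spls(
    data: PairedDataset,
    n_dim: int,
    mode: str = "can",
    keep_x=None,
    keep_y=None,
) -> ProjectionFit:
    """Sparse PLS: exactly ``keep_x[l]`` X-loadings and ``keep_y[l]``
    Y-loadings are nonzero on dimension l.  Scalars broadcast across
    dimensions; None keeps every variable (plain PLS)."""
    keep_x = _norm_keep(keep_x, n_dim, data.p, "keepX")
    keep_y = _norm_keep(keep_y, n_dim, data.q, "keepY")
    return _fit_pls_family(data, n_dim, mode, f"spls-{mode}", keep_x, keep_y)
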