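"""Variable coordinates on reference variates and the pair-wise similarity
matrix M.

Every variable is projected onto a small set of reference axes:

* CCA family: the equiangular vectors Z_l = U_l + V_l, which treat the two
  blocks symmetrically;
* PLS family: the X-variates U_l for the X side, and U_l (regression mode)
  or V_l (canonical mode) for the Y side.

A variable's coordinate on axis l is its sample correlation with that
axis.  The similarity between X^j and Y^k over d retained dimensions is
the inner product of their coordinate vectors,

    M[j, k] = sum_l x_l^j * y_l^k,

which approximates the Pearson correlation cor(X^j, Y^k); with regression-
mode PLS at d = rank(X) the identity is exact.  M is oriented p x q (rows
are X variables), matching the factorization M = x y' with x (p x d) and
y (q x d).

For sparse fits the coordinates — and hence M — are restricted to the
variables selected on at least one retained dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import PairedDataset
from .pls import CCA_METHODS, PLS_METHODS, ProjectionFit

__all__ = [
    "VariableCoordinates",
    "SimilarityMatrix",
    "coords_cca",
    "coords_pls",
    "variable_coordinates",
    "similarity_matrix",
    "similarity_from_fit",
    "pls_similarity_closed_form",
]


@dataclass(frozen=True)
class VariableCoordinates:
    """Correlations of one block's variables with d reference axes."""

    values: np.ndarray  # (n_variables, d)
    ids: list[str]
    side: str  # "X" or "Y"
    reference: str  # "Z", "U", or "V"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != len(self.ids):
            raise ValueError("coordinate matrix must be (n_variables, d)")
        if np.abs(v).max(initial=0.0) > 1 + 1e-8:
            raise ValueError("coordinates are correlations and must lie in [-1, 1]")
        norms = np.sqrt((v**2).sum(axis=1))
        if norms.max(initial=0.0) > 1 + 1e-6:
            raise ValueError(
                "coordinate row norm exceeds 1; reference axes are not orthogonal"
            )
        object.__setattr__(self, "values", v)

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{l+1}" for l in range(self.d)]
        return pd.DataFrame(self.values, index=self.ids, columns=cols)


@dataclass(frozen=True)
class SimilarityMatrix:
    """p x q association matrix between X (rows) and Y (columns)."""

    values: np.ndarray
    x_ids: list[str]
    y_ids: list[str]
    d: int
    method: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.x_ids), len(self.y_ids)):
            raise ValueError("similarity matrix shape must match id lists")
        if np.abs(v).max(initial=0.0) > 1 + 1e-8:
            raise ValueError("similarity entries must lie in [-1, 1]")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.x_ids, columns=self.y_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, d: int = 0, method: str = "unknown"):
        return cls(
            frame.to_numpy(float),
            list(map(str, frame.index)),
            list(map(str, frame.columns)),
            d,
            method,
        )


def _cor_columns(mat: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """Correlation of every column of mat with every column of refs."""
    mc = mat - mat.mean(axis=0)
    rc = refs - refs.mean(axis=0)
    num = mc.T @ rc
    den = np.outer(
        np.sqrt((mc**2).sum(axis=0)), np.sqrt((rc**2).sum(axis=0))
    )
    return num / den


def coords_cca(
    fit: ProjectionFit, data: PairedDataset, d: int | None = None
) -> tuple[VariableCoordinates, VariableCoordinates]:
    """Coordinates on the equiangular axes Z_l = U_l + V_l of a (r)CCA fit."""
    if fit.method not in CCA_METHODS:
        raise ValueError(f"coords_cca requires a CCA-family fit, got {fit.method!r}")
    d = _check_d(fit, d)
    z = fit.u[:, :d] + fit.v[:, :d]
    cx = VariableCoordinates(_cor_columns(data.x, z), data.x_ids, "X", "Z")
    cy = VariableCoordinates(_cor_columns(data.y, z), data.y_ids, "Y", "Z")
    return cx, cy


def coords_pls(
    fit: ProjectionFit, data: PairedDataset, d: int | None = None
) -> tuple[VariableCoordinates, VariableCoordinates]:
    """Coordinates of a PLS-family fit.

    X variables correlate with the X-variates U; Y variables with U in
    regression mode and with their own variates V in canonical mode.  For
    sparse fits only the selected variables get coordinates.
    """
    if fit.method not in PLS_METHODS:
        raise ValueError(f"coords_pls requires a PLS-family fit, got {fit.method!r}")
    d = _check_d(fit, d)
    y_ref = fit.u[:, :d] if fit.mode == "reg" else fit.v[:, :d]
    x_mat, x_ids = data.x, data.x_ids
    y_mat, y_ids = data.y, data.y_ids
    if fit.is_sparse:
        xsel = [j for j in range(data.p) if (fit.a[j, :d] != 0).any()]
        ysel = [k for k in range(data.q) if (fit.b[k, :d] != 0).any()]
        x_mat, x_ids = x_mat[:, xsel], [x_ids[j] for j in xsel]
        y_mat, y_ids = y_mat[:, ysel], [y_ids[k] for k in ysel]
    ref_y_name = "U" if fit.mode == "reg" else "V"
    cx = VariableCoordinates(_cor_columns(x_mat, fit.u[:, :d]), x_ids, "X", "U")
    cy = VariableCoordinates(_cor_columns(y_mat, y_ref), y_ids, "Y", ref_y_name)
    return cx, cy


def variable_coordinates(fit, data, d=None):
    """Dispatch to :func:`coords_cca` or :func:`coords_pls` by fit method."""
    if fit.method in CCA_METHODS:
        return coords_cca(fit, data, d)
    return coords_pls(fit, data, d)


def _check_d(fit, d):
    if d is None:
        return fit.n_dim
    if not 1 <= d <= fit.n_dim:
        raise ValueError(f"d must be in [1, {fit.n_dim}], got {d}")
    return int(d)


_COMPATIBLE_REFS = {("Z", "Z"), ("U", "U"), ("U", "V")}


def similarity_matrix(
    coords_x: VariableCoordinates, coords_y: VariableCoordinates
) -> SimilarityMatrix:
    """M = coords_X @ coords_Y' over the shared retained dimensions."""
    if coords_x.d != coords_y.d:
        raise ValueError(
            f"dimension mismatch: X has d={coords_x.d}, Y has d={coords_y.d}"
        )
    if (coords_x.reference, coords_y.reference) not in _COMPATIBLE_REFS:
        raise ValueError(
            f"incompatible reference families: {coords_x.reference!r} vs "
            f"{coords_y.reference!r}"
        )
    # Bessel's bound on the coordinate rows already caps |M| at 1
    m = coords_x.values @ coords_y.values.T
    return SimilarityMatrix(m, coords_x.ids, coords_y.ids, coords_x.d, "coords")


def similarity_from_fit(
    fit: ProjectionFit, data: PairedDataset, d: int | None = None
) -> SimilarityMatrix:
    """One-call similarity matrix for any fit method."""
    cx, cy = variable_coordinates(fit, data, d)
    m = similarity_matrix(cx, cy)
    return SimilarityMatrix(m.values, m.x_ids, m.y_ids, m.d, fit.method)


def pls_similarity_closed_form(
    fit: ProjectionFit, d: int | None = None, printed_form: bool = False
) -> np.ndarray:
    """Similarity via the stored regression coefficients instead of
    empirical correlations (test oracle; full p x q, ignores sparsity
    restriction).

    Regression mode: M = sum_l u_l^2 phi_l psi_l'.  Canonical mode uses
    u_l sigma_l phi_l psi_l', consistent with coordinates x = u_l phi and
    y = sigma_l psi.  ``printed_form=True`` switches the canonical-mode
    weight to u_l^2 sigma_l^2, a published variant inconsistent with those
    coordinate definitions; it is provided for comparison only.
    """
    if fit.method not in PLS_METHODS:
        raise ValueError("closed form applies to PLS-family fits")
    d = _check_d(fit, d)
    m = np.zeros((fit.a.shape[0], fit.b.shape[0]))
    for l in range(d):
        if fit.mode == "reg":
            w = fit.u_sd[l] ** 2
        elif printed_form:
            w = fit.u_sd[l] ** 2 * fit.v_sd[l] ** 2
        else:
            w = fit.u_sd[l] * fit.v_sd[l]
        m += w * np.outer(fit.phi[:, l], fit.psi[:, l])
    return m
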