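"""Synthetic paired datasets with block cross-correlation structure.

The default :class:`SimulationDesign` draws n=30 samples of two blocks:
X holds three groups of 10, 10 and 3 relevant variables padded with 77
independent noise variables (p=100); Y holds matched groups of 10, 5 and 2
relevant variables padded with 33 noise variables (q=50).  Group A pairs are
negatively cross-correlated (entries in [-0.93, -0.51]), group B positively
([0.5, 0.85]) and group C with mixed signs (|r| in [0.81, 0.93]; X_C is
positively correlated with YC1 and negatively with YC2).

Each matched group is driven by one shared latent factor.  X-side loadings
a_i and Y-side loadings b_k are spaced on a square-root scale so that every
cross-correlation a_i * b_k falls inside the group's magnitude range, with
the extreme magnitude attained exactly at the pair of largest loadings.
This construction yields a positive semi-definite correlation matrix by
construction, which a naive "fill the block with arbitrary values in the
range" approach does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import PairedDataset

__all__ = ["BlockSpec", "SimulationDesign", "build_covariance", "simulate_pair"]

NOISE_PREFIX = "noise_"


@dataclass(frozen=True)
class BlockSpec:
    """One matched group of cross-correlated X and Y variables.

    ``corr_range`` is the (low, high) magnitude range of the pair-wise
    cross-correlations; ``y_signs`` gives the sign of the correlation of
    each Y variable in the group with every X variable of the group.
    """

    n_x: int
    n_y: int
    corr_range: tuple[float, float]
    y_signs: tuple[int, ...]

    def __post_init__(self):
        lo, hi = self.corr_range
        if self.n_x <= 0 or self.n_y <= 0:
            raise ValueError("block sizes must be positive")
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"correlation magnitude range must satisfy 0 <= low <= high <= 1, got {self.corr_range}")
        if len(self.y_signs) != self.n_y or any(s not in (-1, 1) for s in self.y_signs):
            raise ValueError("y_signs must hold one value in {-1, +1} per Y variable")

    def loadings(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.corr_range
        a = np.linspace(np.sqrt(lo), np.sqrt(hi), self.n_x)
        b = np.linspace(np.sqrt(lo), np.sqrt(hi), self.n_y)
        return a, b


def _default_blocks():
    return (
        BlockSpec(10, 10, (0.51, 0.93), tuple([-1] * 10)),
        BlockSpec(10, 5, (0.50, 0.85), tuple([1] * 5)),
        BlockSpec(3, 2, (0.81, 0.93), (1, -1)),
    )


@dataclass(frozen=True)
class SimulationDesign:
    """Full description of a paired-simulation draw.

    Parameters
    ----------
    n_samples
        Number of rows drawn for both blocks.
    blocks
        One :class:`BlockSpec` per matched group of relevant variables.
    n_noise_x, n_noise_y
        Independent standard-normal padding columns appended after the
        relevant groups.
    within_corr
        Optional target within-group correlation level in (0, 1).  When
        set, a second group-private factor raises within-group correlation
        toward this level wherever the shared-factor loadings leave room;
        when None (default) within-group correlation is whatever the shared
        factor induces.
    repair_tol
        Maximum distortion of a targeted cross-correlation tolerated when
        eigenvalue clipping has to repair a non-PSD matrix.
    fill
        ``"factor"`` (default): latent-factor construction, PSD by
        construction.  ``"linspace"``: within-blocks compound-symmetric at
        ``within_corr`` and cross-blocks filled with evenly spaced values
        across the range; such matrices are generally not PSD and go
        through eigenvalue-clipping repair, which rejects the design when
        the repair distorts a targeted entry beyond ``repair_tol``.
    """

    n_samples: int = 30
    blocks: tuple[BlockSpec, ...] = field(default_factory=_default_blocks)
    n_noise_x: int = 77
    n_noise_y: int = 33
    within_corr: float | None = None
    repair_tol: float = 0.02
    fill: str = "factor"
    seed: int = 42

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("need at least two samples")
        if self.n_noise_x < 0 or self.n_noise_y < 0:
            raise ValueError("noise counts must be nonnegative")
        if self.within_corr is not None and not (0.0 < self.within_corr < 1.0):
            raise ValueError("within_corr must lie in (0, 1)")
        if self.fill not in ("factor", "linspace"):
            raise ValueError("fill must be 'factor' or 'linspace'")

    @property
    def p(self) -> int:
        return sum(b.n_x for b in self.blocks) + self.n_noise_x

    @property
    def q(self) -> int:
        return sum(b.n_y for b in self.blocks) + self.n_noise_y

    def x_offsets(self):
        off = []
        o = 0
        for b in self.blocks:
            off.append(o)
            o += b.n_x
        return off

    def y_offsets(self):
        off = []
        o = 0
        for b in self.blocks:
            off.append(o)
            o += b.n_y
        return off

    @classmethod
    def from_yaml(cls, path) -> "SimulationDesign":
        """Load a design from YAML.  Block entries use the keys ``n_x``,
        ``n_y``, ``range`` ([low, high] magnitudes) and ``y_signs``; all
        other top-level keys mirror the constructor arguments."""
        import yaml

        raw = yaml.safe_load(open(path)) or {}
        if "blocks" in raw:
            raw["blocks"] = tuple(
                BlockSpec(
                    int(b["n_x"]),
                    int(b["n_y"]),
                    tuple(float(v) for v in b["range"]),
                    tuple(int(s) for s in b["y_signs"]),
                )
                for b in raw["blocks"]
            )
        return cls(**raw)

    def variable_ids(self) -> tuple[list[str], list[str]]:
        """Ids encode group membership; noise columns carry NOISE_PREFIX."""
        letters = "ABCDEFGH"
        x_ids, y_ids = [], []
        for g, b in enumerate(self.blocks):
            x_ids += [f"X{letters[g]}{i+1}" for i in range(b.n_x)]
            y_ids += [f"Y{letters[g]}{i+1}" for i in range(b.n_y)]
        x_ids += [f"{NOISE_PREFIX}X{i+1}" for i in range(self.n_noise_x)]
        y_ids += [f"{NOISE_PREFIX}Y{i+1}" for i in range(self.n_noise_y)]
        return x_ids, y_ids


def _factor_loadings(design: SimulationDesign) -> np.ndarray:
    """(p+q) x n_factor loading matrix whose Gram matrix (plus idiosyncratic
    diagonal) is the target correlation matrix."""
    p, q = design.p, design.q
    cols = []
    xo, yo = design.x_offsets(), design.y_offsets()
    for g, b in enumerate(design.blocks):
        a, bl = b.loadings()
        v = np.zeros(p + q)
        v[xo[g]:xo[g] + b.n_x] = a
        v[p + yo[g]:p + yo[g] + b.n_y] = np.array(b.y_signs, dtype=float) * bl
        cols.append(v)
        if design.within_corr is not None:
            w = design.within_corr
            gx = np.zeros(p + q)
            gx[xo[g]:xo[g] + b.n_x] = np.sqrt(np.clip(w - a**2, 0.0, None))
            gy = np.zeros(p + q)
            gy[p + yo[g]:p + yo[g] + b.n_y] = np.sqrt(np.clip(w - bl**2, 0.0, None))
            cols.append(gx)
            cols.append(gy)
    return np.column_stack(cols)


def _target_cross_mask(design: SimulationDesign) -> np.ndarray:
    """Boolean (p+q)x(p+q) mask of the targeted cross-correlation entries."""
    p, q = design.p, design.q
    mask = np.zeros((p + q, p + q), dtype=bool)
    xo, yo = design.x_offsets(), design.y_offsets()
    for g, b in enumerate(design.blocks):
        rows = slice(xo[g], xo[g] + b.n_x)
        cols = slice(p + yo[g], p + yo[g] + b.n_y)
        mask[rows, cols] = True
        mask[cols, rows] = True
    return mask


def build_covariance(design: SimulationDesign) -> np.ndarray:
    """Assemble the (p+q) x (p+q) correlation matrix of the design.

    The relevant groups follow the latent-factor construction described in
    the module docstring; noise variables are independent of everything.
    The matrix has unit diagonal, symmetric by construction; any residual
    non-PSD-ness (possible only with an aggressive ``within_corr``) is
    repaired by clipping eigenvalues below 1e-8 and rescaling to unit
    diagonal.  Repair that moves a targeted cross-correlation by more than
    ``design.repair_tol`` raises ValueError.
    """
    if design.fill == "linspace":
        sigma = _linspace_sigma(design)
    else:
        L = _factor_loadings(design)
        communality = (L**2).sum(axis=1)
        if communality.max() > 1.0 + 1e-12:
            raise ValueError(
                "factor loadings exceed unit variance; lower within_corr or the correlation ranges"
            )
        sigma = L @ L.T
        np.fill_diagonal(sigma, 1.0)
    w = np.linalg.eigvalsh(sigma)
    if w.min() < -1e-10:
        sigma = _psd_repair(sigma, design)
    return sigma


def _linspace_sigma(design: SimulationDesign) -> np.ndarray:
    w = design.within_corr if design.within_corr is not None else 0.8
    p, q = design.p, design.q
    sigma = np.eye(p + q)
    xo, yo = design.x_offsets(), design.y_offsets()
    for g, b in enumerate(design.blocks):
        for off, k in ((xo[g], b.n_x), (p + yo[g], b.n_y)):
            block = np.full((k, k), w)
            np.fill_diagonal(block, 1.0)
            sigma[off:off + k, off:off + k] = block
        lo, hi = b.corr_range
        vals = np.linspace(lo, hi, b.n_x * b.n_y).reshape(b.n_x, b.n_y)
        cross = vals * np.array(b.y_signs, dtype=float)
        sigma[xo[g]:xo[g] + b.n_x, p + yo[g]:p + yo[g] + b.n_y] = cross
        sigma[p + yo[g]:p + yo[g] + b.n_y, xo[g]:xo[g] + b.n_x] = cross.T
    return sigma


def _psd_repair(sigma: np.ndarray, design: SimulationDesign) -> np.ndarray:
    w, v = np.linalg.eigh(sigma)
    repaired = (v * np.clip(w, 1e-8, None)) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    mask = _target_cross_mask(design)
    distortion = np.abs(repaired[mask] - sigma[mask]).max() if mask.any() else 0.0
    if distortion > design.repair_tol:
        raise ValueError(
            f"PSD repair distorted targeted cross-correlations by {distortion:.4f} "
            f"(> tolerance {design.repair_tol}); the design is infeasible"
        )
    return repaired


def cross_covariance(design: SimulationDesign) -> np.ndarray:
    """The p x q cross block Sigma_XY of :func:`build_covariance`."""
    sigma = build_covariance(design)
    return sigma[: design.p, design.p:]


def simulate_pair(design: SimulationDesign, seed: int | None = None) -> PairedDataset:
    """Draw one paired dataset from the design's multivariate normal.

    Returns a standardized :class:`PairedDataset`; variable ids encode
    group membership (e.g. ``XA1``..``XA10``) and noise columns carry the
    ``noise_`` prefix so downstream network tests can count them.
    """
    if seed is None:
        seed = design.seed
    sigma = build_covariance(design)
    w = np.linalg.eigvalsh(sigma)
    if w.min() < -1e-8:
        raise ValueError("covariance matrix is not positive semi-definite")
    rng = np.random.default_rng(seed)
    # jitter keeps Cholesky stable for exactly singular factor structures
    chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(sigma.shape[0]))
    draws = rng.standard_normal((design.n_samples, sigma.shape[0])) @ chol.T
    x_ids, y_ids = design.variable_ids()
    ds = PairedDataset(
        draws[:, : design.p],
        draws[:, design.p:],
        sample_ids=[f"s{i+1}" for i in range(design.n_samples)],
        x_ids=x_ids,
        y_ids=y_ids,
    )
    return ds.standardize()
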