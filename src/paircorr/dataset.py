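"""Container for two numeric matrices measured on the same samples.

The two blocks are conventionally called X (n samples x p variables, e.g.
gene expression) and Y (n x q, e.g. metabolite concentrations or clinical
measurements).  All fitting routines in this package expect column-wise
standardized data; :meth:`PairedDataset.standardize` produces it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["PairedDataset"]


def _check_ids(ids, what):
    ids = list(map(str, ids))
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what} ids: {dup[:5]}")
    return ids


@dataclass(frozen=True)
class PairedDataset:
    """Two paired blocks sharing the same samples (rows).

    Parameters
    ----------
    x, y
        Numeric matrices of shape (n, p) and (n, q).
    sample_ids, x_ids, y_ids
        Row and column labels; duplicates are rejected.
    standardized
        True when every column has zero mean and unit variance (ddof=1).
    """

    x: np.ndarray
    y: np.ndarray
    sample_ids: list[str] = field(default=None)
    x_ids: list[str] = field(default=None)
    y_ids: list[str] = field(default=None)
    standardized: bool = False

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 2 or y.ndim != 2:
            raise ValueError("X and Y must be 2-dimensional")
        if x.shape[0] != y.shape[0]:
            raise ValueError(
                f"X and Y must share samples: {x.shape[0]} vs {y.shape[0]} rows"
            )
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("X and Y must contain only finite values")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        n, p = x.shape
        q = y.shape[1]
        sid = self.sample_ids if self.sample_ids is not None else [f"s{i+1}" for i in range(n)]
        xid = self.x_ids if self.x_ids is not None else [f"X{j+1}" for j in range(p)]
        yid = self.y_ids if self.y_ids is not None else [f"Y{k+1}" for k in range(q)]
        sid = _check_ids(sid, "sample")
        xid = _check_ids(xid, "X variable")
        yid = _check_ids(yid, "Y variable")
        if len(sid) != n or len(xid) != p or len(yid) != q:
            raise ValueError("id list lengths do not match matrix shapes")
        object.__setattr__(self, "sample_ids", sid)
        object.__setattr__(self, "x_ids", xid)
        object.__setattr__(self, "y_ids", yid)
        if self.standardized:
            self._assert_standardized()

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def p(self) -> int:
        return self.x.shape[1]

    @property
    def q(self) -> int:
        return self.y.shape[1]

    def _assert_standardized(self, tol=1e-8):
        for m, name in ((self.x, "X"), (self.y, "Y")):
            if np.abs(m.mean(axis=0)).max() > tol:
                raise ValueError(f"{name} columns are not centered")
            v = m.var(axis=0, ddof=1)
            if np.abs(v - 1.0).max() > tol:
                raise ValueError(f"{name} columns do not have unit variance")

    def standardize(self) -> "PairedDataset":
        """Return a copy with every column centered and scaled to unit
        variance (ddof=1).  Zero-variance columns are rejected by name."""
        if self.standardized:
            return self
        mats = []
        for m, ids, name in ((self.x, self.x_ids, "X"), (self.y, self.y_ids, "Y")):
            mu = m.mean(axis=0)
            sd = m.std(axis=0, ddof=1)
            zero = np.flatnonzero(sd == 0)
            if zero.size:
                bad = [ids[j] for j in zero[:5]]
                raise ValueError(f"zero-variance {name} column(s): {bad}")
            mats.append((m - mu) / sd)
        return replace(self, x=mats[0], y=mats[1], standardized=True)

    # -- interop --------------------------------------------------------
    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        fx = pd.DataFrame(self.x, index=self.sample_ids, columns=self.x_ids)
        fy = pd.DataFrame(self.y, index=self.sample_ids, columns=self.y_ids)
        return fx, fy

    @classmethod
    def from_frames(cls, fx: pd.DataFrame, fy: pd.DataFrame, standardized=False):
        if list(fx.index) != list(fy.index):
            raise ValueError("frames must share an identical sample index")
        return cls(
            fx.to_numpy(float),
            fy.to_numpy(float),
            sample_ids=list(map(str, fx.index)),
            x_ids=list(map(str, fx.columns)),
            y_ids=list(map(str, fy.columns)),
            standardized=standardized,
        )
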