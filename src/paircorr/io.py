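"""Delimited-matrix input/output and fit serialization.

Matrices travel as TSV/CSV with a header row of variable ids and a first
column of sample ids.  Fits are serialized to JSON at full float precision
(Python's repr round-trip), so a pipeline can be split across separate
process invocations without numeric drift.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import PairedDataset
from .pls import ProjectionFit
from .similarity import SimilarityMatrix

__all__ = [
    "read_matrix",
    "read_paired",
    "write_dataset",
    "write_similarity",
    "read_similarity",
    "fit_to_json",
    "fit_from_json",
]


def read_matrix(path, sep=None) -> pd.DataFrame:
    """One delimited matrix: first column sample ids, header variable ids.

    ``sep=None`` auto-detects the delimiter (tab or comma).
    """
    if sep is None:
        with open(path) as handle:
            header = handle.readline()
        sep = "\t" if header.count("\t") >= header.count(",") else ","
    frame = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    frame.index = frame.index.map(str)
    frame.columns = frame.columns.map(str)
    bad = [c for c in frame.columns if not pd.api.types.is_numeric_dtype(frame[c])]
    if bad:
        raise ValueError(f"{path}: non-numeric column(s): {bad[:5]}")
    if frame.isna().any().any():
        raise ValueError(f"{path}: missing or non-numeric cells present")
    if frame.index.duplicated().any():
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids: {dups[:5]}")
    return frame


def read_paired(path_x, path_y, standardize: bool = True, sep=None) -> PairedDataset:
    """Read the two blocks and align their samples by id.

    Rows of Y are reordered to X's sample order; a sample present in one
    file but not the other is an error naming the sample id.
    """
    fx = read_matrix(path_x, sep=sep)
    fy = read_matrix(path_y, sep=sep)
    sx, sy = set(fx.index), set(fy.index)
    if sx != sy:
        missing_y = sorted(sx - sy)
        missing_x = sorted(sy - sx)
        parts = []
        if missing_y:
            parts.append(f"samples missing from {path_y}: {missing_y[:5]}")
        if missing_x:
            parts.append(f"samples missing from {path_x}: {missing_x[:5]}")
        raise ValueError("; ".join(parts))
    fy = fy.loc[fx.index]
    ds = PairedDataset.from_frames(fx, fy)
    return ds.standardize() if standardize else ds


def write_dataset(data: PairedDataset, path_x, path_y, sep="\t") -> None:
    fx, fy = data.to_frames()
    fx.to_csv(path_x, sep=sep, index_label="sample")
    fy.to_csv(path_y, sep=sep, index_label="sample")


def write_similarity(m: SimilarityMatrix, path, sep="\t") -> None:
    m.to_frame().to_csv(path, sep=sep, index_label="")


def read_similarity(path, sep="\t") -> SimilarityMatrix:
    frame = pd.read_csv(path, sep=sep, index_col=0)
    frame.index = frame.index.map(str)
    frame.columns = frame.columns.map(str)
    return SimilarityMatrix.from_frame(frame)


_ARRAY_FIELDS = ("a", "b", "u", "v", "rho", "phi", "psi", "u_sd", "v_sd", "y_residual_norms")


def fit_to_json(fit: ProjectionFit, path=None) -> str:
    """Serialize a fit to a JSON string, optionally writing it to path."""
    payload = {
        "method": fit.method,
        "n_dim": fit.n_dim,
        "x_ids": fit.x_ids,
        "y_ids": fit.y_ids,
        "keep_x": list(fit.keep_x) if fit.keep_x is not None else None,
        "keep_y": list(fit.keep_y) if fit.keep_y is not None else None,
        "lambda1": fit.lambda1,
        "lambda2": fit.lambda2,
    }
    for name in _ARRAY_FIELDS:
        arr = getattr(fit, name)
        payload[name] = arr.tolist() if arr is not None else None
    text = json.dumps(payload)
    if path is not None:
        Path(path).write_text(text)
    return text


def fit_from_json(source) -> ProjectionFit:
    """Inverse of :func:`fit_to_json`; accepts a path or a JSON string."""
    text = source
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("{")
    ):
        text = Path(source).read_text()
    payload = json.loads(text)
    kwargs = {
        "method": payload["method"],
        "n_dim": payload["n_dim"],
        "x_ids": payload["x_ids"],
        "y_ids": payload["y_ids"],
        "keep_x": tuple(payload["keep_x"]) if payload.get("keep_x") else None,
        "keep_y": tuple(payload["keep_y"]) if payload.get("keep_y") else None,
        "lambda1": payload.get("lambda1"),
        "lambda2": payload.get("lambda2"),
    }
    for name in _ARRAY_FIELDS:
        val = payload.get(name)
        kwargs[name] = np.asarray(val, dtype=float) if val is not None else None
    return ProjectionFit(**kwargs)
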