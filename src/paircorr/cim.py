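"""Clustered Image Map: dual hierarchical clustering of the similarity
matrix with a dendrogram-ordered heatmap.

Rows and columns of M are clustered independently (default: Euclidean
distance, Ward linkage in the ward.D2 convention, i.e. the Lance-Williams
recurrence on squared Euclidean distances with square-rooted merge
heights).  Leaves are ordered by a deterministic rule: within each merge
the subtree with the lower merge height comes first, ties broken by the
smallest leaf index.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np
from matplotlib.colors import LinearSegmentedColormap
from scipy.cluster.hierarchy import dendrogram, linkage
from scipy.spatial.distance import pdist

from .similarity import SimilarityMatrix

__all__ = ["CIMResult", "cluster_similarity", "render_cim"]

_METRICS = {"euclidean", "cityblock", "correlation", "cosine"}
_LINKAGES = {"ward", "single", "complete", "average"}

#: red (negative) through yellow (zero) to green (positive), per the
#: conventional correlation heatmap legend
CIM_CMAP = LinearSegmentedColormap.from_list(
    "cim", ["#b2182b", "#f7f07a", "#1a9641"]
)


@dataclass(frozen=True)
class CIMResult:
    """Dual-clustering result: permutations, merge trees, reordered M."""

    matrix: np.ndarray  # reordered
    row_perm: np.ndarray
    col_perm: np.ndarray
    row_linkage: np.ndarray  # scipy linkage matrices
    col_linkage: np.ndarray
    row_ids: list[str]  # in reordered order
    col_ids: list[str]
    metric: str
    method: str


def _leaf_order(z: np.ndarray, n: int) -> list[int]:
    """Deterministic leaf ordering from a scipy linkage matrix.

    At every internal node the child with the smaller merge height is
    placed first (leaves have height 0); ties break on the smallest leaf
    index in the subtree.
    """
    height = {i: 0.0 for i in range(n)}
    children = {}
    minleaf = {i: i for i in range(n)}
    for step, (a, b, h, _) in enumerate(z):
        node = n + step
        a, b = int(a), int(b)
        key_a = (height[a], minleaf[a])
        key_b = (height[b], minleaf[b])
        first, second = (a, b) if key_a <= key_b else (b, a)
        children[node] = (first, second)
        height[node] = float(h)
        minleaf[node] = min(minleaf[a], minleaf[b])
    order: list[int] = []
    stack = [n + len(z) - 1] if len(z) else [0]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
        else:
            first, second = children[node]
            stack.append(second)
            stack.append(first)
    return order


def cluster_similarity(
    m: SimilarityMatrix, metric: str = "euclidean", method: str = "ward"
) -> CIMResult:
    """Cluster the rows and the columns of M independently."""
    if metric not in _METRICS:
        raise ValueError(f"unknown distance metric {metric!r}; choose from {sorted(_METRICS)}")
    if method not in _LINKAGES:
        raise ValueError(f"unknown linkage {method!r}; choose from {sorted(_LINKAGES)}")
    vals = m.values
    if vals.shape[0] < 2 or vals.shape[1] < 2:
        raise ValueError("CIM needs at least 2 rows and 2 columns")
    zr = linkage(pdist(vals, metric=metric), method=method)
    zc = linkage(pdist(vals.T, metric=metric), method=method)
    row_perm = np.array(_leaf_order(zr, vals.shape[0]))
    col_perm = np.array(_leaf_order(zc, vals.shape[1]))
    return CIMResult(
        matrix=vals[np.ix_(row_perm, col_perm)],
        row_perm=row_perm,
        col_perm=col_perm,
        row_linkage=zr,
        col_linkage=zc,
        row_ids=[m.x_ids[i] for i in row_perm],
        col_ids=[m.y_ids[i] for i in col_perm],
        metric=metric,
        method=method,
    )


def render_cim(result: CIMResult, path, cmap=None, figsize=(9, 8)) -> None:
    """Heatmap of the reordered matrix with dendrograms on top and left.

    The color scale is symmetric about zero and saturates at +-1 so the
    sign of an association is always readable regardless of the empirical
    range of M.
    """
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    cmap = cmap or CIM_CMAP
    fig = plt.figure(figsize=figsize)
    gs = fig.add_gridspec(
        2, 3, width_ratios=[1.2, 6, 0.3], height_ratios=[1.2, 6],
        hspace=0.02, wspace=0.02,
    )
    ax_col = fig.add_subplot(gs[0, 1])
    ax_row = fig.add_subplot(gs[1, 0])
    ax_heat = fig.add_subplot(gs[1, 1])
    ax_cbar = fig.add_subplot(gs[1, 2])
    with plt.rc_context({"lines.linewidth": 0.8}):
        dendrogram(result.col_linkage, ax=ax_col, no_labels=True,
                   link_color_func=lambda _: "black")
        dendrogram(result.row_linkage, ax=ax_row, orientation="left",
                   no_labels=True, link_color_func=lambda _: "black")
    ax_col.set_axis_off()
    ax_row.set_axis_off()
    ax_row.invert_yaxis()
    # the drawn dendrograms use scipy's own leaf order, so render the
    # heatmap in that order too; CIMResult keeps the package's canonical
    # deterministic ordering for programmatic use
    from scipy.cluster.hierarchy import leaves_list

    rl = leaves_list(result.row_linkage)
    cl = leaves_list(result.col_linkage)
    inv_row = np.argsort(result.row_perm)
    inv_col = np.argsort(result.col_perm)
    original = result.matrix[np.ix_(inv_row, inv_col)]
    img = ax_heat.imshow(
        original[np.ix_(rl, cl)], cmap=cmap, vmin=-1, vmax=1,
        aspect="auto", interpolation="nearest",
    )
    ax_heat.set_xticks([])
    ax_heat.set_yticks([])
    fig.colorbar(img, cax=ax_cbar)
    fig.savefig(path, dpi=150)
    plt.close(fig)
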