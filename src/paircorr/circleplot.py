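"""Correlation circle plots.

Every variable is drawn at the point given by its correlations with two
chosen reference variates, so all points live inside the unit disk.  Two
guide circles (radii 0.5 and 1) are drawn; the angle between two position
vectors reflects the sign and strength of the correlation between the
variables (sharp angle: positive, obtuse: negative, right angle: weak).
The coordinates are exactly the relevant columns of the similarity
module's :class:`~paircorr.similarity.VariableCoordinates`, so circle,
CIM and network views are always mutually consistent.
"""

from __future__ import annotations

import matplotlib
import numpy as np
import pandas as pd

from .similarity import VariableCoordinates

__all__ = ["circle_coords", "render_circle"]


def circle_coords(
    coords_x: VariableCoordinates,
    coords_y: VariableCoordinates,
    dim_pair: tuple[int, int] = (1, 2),
) -> pd.DataFrame:
    """Two-column coordinate table for a pair of dimensions (1-based).

    Returns a DataFrame with columns ``id``, ``side``, ``x``, ``y``.
    """
    l1, l2 = dim_pair
    if l1 == l2:
        raise ValueError("the two dimensions must differ")
    for coords in (coords_x, coords_y):
        if not (1 <= l1 <= coords.d and 1 <= l2 <= coords.d):
            raise ValueError(f"dimensions {dim_pair} out of range (d={coords.d})")
    rows = []
    for coords in (coords_x, coords_y):
        for i, vid in enumerate(coords.ids):
            rows.append(
                {
                    "id": vid,
                    "side": coords.side,
                    "x": coords.values[i, l1 - 1],
                    "y": coords.values[i, l2 - 1],
                }
            )
    table = pd.DataFrame(rows, columns=["id", "side", "x", "y"])
    radii = np.hypot(table["x"], table["y"])
    if len(table) and radii.max() > 1 + 1e-8:
        raise ValueError("coordinates fall outside the unit disk")
    return table


def render_circle(
    table: pd.DataFrame,
    path,
    threshold: float | None = None,
    labels: bool = False,
    dim_pair: tuple[int, int] = (1, 2),
) -> None:
    """Scatter X variables (dots) and Y variables (triangles) inside the
    radius-0.5 and radius-1 guide circles.

    ``threshold`` hides points whose distance from the origin in the
    plotted plane is below it (weak associations); positions of surviving
    points are unchanged.
    """
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if threshold is not None:
        radii = np.hypot(table["x"], table["y"])
        table = table[radii >= threshold]
    fig, ax = plt.subplots(figsize=(6, 6))
    for radius, style in ((1.0, "-"), (0.5, "--")):
        ax.add_patch(
            plt.Circle((0, 0), radius, fill=False, color="grey", linestyle=style, linewidth=0.8)
        )
    for side, marker, color in (("X", "o", "#1f77b4"), ("Y", "^", "#d62728")):
        sub = table[table["side"] == side]
        ax.scatter(sub["x"], sub["y"], marker=marker, s=25, color=color, label=side)
        if labels:
            for _, row in sub.iterrows():
                ax.annotate(row["id"], (row["x"], row["y"]), fontsize=6)
    ax.axhline(0, color="grey", linewidth=0.5)
    ax.axvline(0, color="grey", linewidth=0.5)
    ax.set_xlim(-1.1, 1.1)
    ax.set_ylim(-1.1, 1.1)
    ax.set_aspect("equal")
    ax.set_xlabel(f"dimension {dim_pair[0]}")
    ax.set_ylabel(f"dimension {dim_pair[1]}")
    ax.legend(loc="upper right", fontsize=8)
    fig.savefig(path, dpi=150)
    plt.close(fig)
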