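"""Built-in 58-channel scalp layout and channel adjacency.

The built-in montage covers the extended 10-20 (10-10) positions of a
58-channel scalp set (reference/ground/ocular leads excluded), laid out on
the unit disk: anterior is +y, left is -x.  Coordinates are schematic layout
positions — adequate for neighborhood construction and plotting, not for
source modelling.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay

from .io_core import Montage

# rows front -> back: (y coordinate, labels left -> right)
_ROWS: list[tuple[float, list[str]]] = [
    (0.90, ["Fp1", "Fpz", "Fp2"]),
    (0.72, ["AF7", "AF3", "AF4", "AF8"]),
    (0.50, ["F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8"]),
    (0.25, ["FT7", "FC5", "FC3", "FC1", "FC2", "FC4", "FC6", "FT8"]),
    (0.00, ["T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8"]),
    (-0.25, ["TP7", "CP5", "CP3", "CP1", "CP2", "CP4", "CP6", "TP8"]),
    (-0.50, ["P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8"]),
    (-0.72, ["PO7", "PO3", "POz", "PO4", "PO8"]),
    (-0.90, ["O1", "Oz", "O2"]),
]


def standard_montage_58() -> Montage:
    """The package's built-in 58-channel 10-10 montage."""
    labels: list[str] = []
    xy: list[tuple[float, float]] = []
    for y, row in _ROWS:
        half_width = 0.92 * np.sqrt(max(1.0 - y * y, 0.0))
        if len(row) == 1:
            xs = np.array([0.0])
        else:
            xs = np.linspace(-half_width, half_width, len(row))
        for lbl, x in zip(row, xs):
            labels.append(lbl)
            xy.append((float(x), float(y)))
    return Montage(labels, np.array(xy))


def channel_adjacency(montage: Montage,
                      max_edge_factor: float = 1.5) -> np.ndarray:
    """Symmetric boolean channel-neighborhood matrix.

    Neighbors are the edges of the Delaunay triangulation of the 2-D layout,
    with edges longer than ``max_edge_factor`` times the median edge length
    removed (this prevents spurious long links across the head outline).
    """
    n = montage.n_channels
    adj = np.zeros((n, n), dtype=bool)
    if n < 3:
        adj[:] = ~np.eye(n, dtype=bool)
        return adj
    tri = Delaunay(montage.xy)
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = simplex[i], simplex[(i + 1) % 3]
            edges.add((min(a, b), max(a, b)))
    edges = np.array(sorted(edges))
    lengths = np.linalg.norm(
        montage.xy[edges[:, 0]] - montage.xy[edges[:, 1]], axis=1
    )
    keep = lengths <= max_edge_factor * np.median(lengths)
    for (a, b) in edges[keep]:
        adj[a, b] = adj[b, a] = True
    return adj


def plot_topography(montage: Montage, values, ax=None, cmap="RdBu_r"):
    """Quick filled-contour scalp map of one per-channel vector."""
    import matplotlib.pyplot as plt

    values = np.asarray(values, dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    x, y = montage.xy[:, 0], montage.xy[:, 1]
    good = np.isfinite(values)
    tcf = ax.tricontourf(x[good], y[good], values[good], levels=20, cmap=cmap)
    ax.scatter(x, y, s=6, c="k", zorder=3)
    circle = plt.Circle((0, 0), 1.0, fill=False, color="k")
    ax.add_patch(circle)
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.figure.colorbar(tcf, ax=ax, shrink=0.7)
    return ax
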