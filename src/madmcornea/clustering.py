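"""Density-based cluster/dispersion analysis of single-labeled cells.

Implements the DBSCAN-style clustering used to quantify how tightly the
progeny of MADM recombination events pack together, and the
percent-in-cluster dispersion statistic: the fraction of single-labeled
cells of one color that belong to any density cluster.

The construction is the classic one — a *core* point has at least
``min_density`` points (itself included) within ``eps``; clusters are the
connected components of core points under eps-reachability; non-core
points within eps of a core join its cluster — with one deviation from
textbook DBSCAN: border points reachable from several clusters are
assigned to the cluster of their nearest core point (ties broken by lowest
point index), which makes the output independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

NOISE = -1


@dataclass(frozen=True)
class ClusteringParams:
    """ε-neighborhood radius (um) and minimum neighborhood occupancy.

    ``min_density`` counts the query point itself, matching the reading of
    "minimum density = 4 (minimum cluster size)": every cluster then has at
    least ``min_density`` members.  Set ``inclusive=False`` for the
    exclusive convention.
    """

    eps: float = 45.0 * (248.0 / 82.0)  # 136 um
    min_density: int = 4
    color_scope: str = "separate"  # "separate" or "pooled"
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_density < 2:
            raise ValueError("min_density must be >= 2")
        if self.color_scope not in ("separate", "pooled"):
            raise ValueError("color_scope must be 'separate' or 'pooled'")


@dataclass
class ClusterAssignment:
    """Per-point cluster labels (>= 0) with -1 marking noise."""

    labels: np.ndarray
    params: ClusteringParams
    is_core: np.ndarray = field(default=None)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def cluster_sizes(self) -> np.ndarray:
        if self.n_clusters == 0:
            return np.zeros(0, dtype=int)
        return np.bincount(self.labels[self.labels >= 0], minlength=self.n_clusters)

    def cluster_centroids(self, points: np.ndarray) -> np.ndarray:
        cents = np.empty((self.n_clusters, 2))
        for k in range(self.n_clusters):
            cents[k] = points[self.labels == k].mean(axis=0)
        return cents


def sidc_cluster(points: np.ndarray, params: ClusteringParams | None = None) -> ClusterAssignment:
    """Order-independent density-based clustering of 2D positions (um).

    Operates on point centroids only, so the result is invariant to the
    size and shape of the detected blobs the points came from.
    """
    params = params or ClusteringParams()
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(points)
    if n == 0:
        return ClusterAssignment(labels=np.empty(0, dtype=int), params=params,
                                 is_core=np.empty(0, dtype=bool))
    if not np.all(np.isfinite(points)):
        raise ValueError("coordinates must be finite")

    tree = cKDTree(points)
    neighbors = tree.query_ball_point(points, r=params.eps)  # includes self
    counts = np.fromiter((len(nb) for nb in neighbors), dtype=int, count=n)
    min_nb = params.min_density if params.inclusive else params.min_density + 1
    is_core = counts >= min_nb

    labels = np.full(n, NOISE, dtype=int)
    core_idx = np.flatnonzero(is_core)
    if core_idx.size:
        # connected components of core points under eps-reachability
        pos_of = np.full(n, -1)
        pos_of[core_idx] = np.arange(core_idx.size)
        rows, cols = [], []
        for i in core_idx:
            for j in neighbors[i]:
                if is_core[j]:
                    rows.append(pos_of[i])
                    cols.append(pos_of[j])
        adj = coo_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)),
                         shape=(core_idx.size, core_idx.size))
        n_comp, comp = connected_components(adj, directed=False)
        # canonical labels: order clusters by their lowest member index
        first = np.full(n_comp, n)
        for pos, i in enumerate(core_idx):
            first[comp[pos]] = min(first[comp[pos]], i)
        relabel = np.argsort(np.argsort(first))
        labels[core_idx] = relabel[comp]

        # border points: nearest core within eps, ties to the lowest index
        core_tree = cKDTree(points[core_idx])
        for i in np.flatnonzero(~is_core):
            cores_near = [j for j in neighbors[i] if is_core[j]]
            if not cores_near:
                continue
            d = np.hypot(*(points[cores_near] - points[i]).T)
            best = min(zip(d, cores_near))  # distance then index tie-break
            labels[i] = labels[best[1]]

    return ClusterAssignment(labels=labels, params=params, is_core=is_core)


def percent_in_clusters(assignment: ClusterAssignment,
                        mask: np.ndarray | None = None) -> float | None:
    """Percentage of points (optionally restricted by a boolean mask)
    assigned to any cluster.  ``None`` when the subset is empty."""
    labels = assignment.labels
    if mask is not None:
        labels = labels[np.asarray(mask, dtype=bool)]
    if labels.size == 0:
        return None
    return 100.0 * float(np.count_nonzero(labels >= 0)) / labels.size


def cluster_cells(cells: pd.DataFrame, params: ClusteringParams | None = None
                  ) -> tuple[pd.DataFrame, dict]:
    """Cluster a detections table (columns x_um, y_um, class) per color.

    Returns the table with a ``cluster_id`` column (noise = -1; cluster ids
    are unique across colors when clustered separately) and a summary dict
    with per-color percent-in-cluster and cluster sizes.
    """
    params = params or ClusteringParams()
    cells = cells.copy()
    singles = cells["class"].isin(["red", "green"])
    cells["cluster_id"] = NOISE
    summary: dict = {"params": {"eps_um": params.eps, "min_density": params.min_density,
                                "color_scope": params.color_scope},
                     "per_color": {}}
    if params.color_scope == "pooled":
        groups = [("pooled", singles)]
    else:
        groups = [(c, singles & (cells["class"] == c)) for c in ("red", "green")]
    offset = 0
    for color, m in groups:
        pts = cells.loc[m, ["x_um", "y_um"]].to_numpy()
        asg = sidc_cluster(pts, params)
        lab = asg.labels.copy()
        lab[lab >= 0] += offset
        cells.loc[m, "cluster_id"] = lab
        offset += asg.n_clusters
        summary["per_color"][color] = {
            "n_points": int(len(pts)),
            "n_clusters": int(asg.n_clusters),
            "cluster_sizes": asg.cluster_sizes().tolist(),
            "percent_in_clusters": percent_in_clusters(asg),
        }
    return cells, summary
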