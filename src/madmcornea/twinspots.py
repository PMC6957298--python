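"""Twin-spot discovery.

A twin spot is the pair of red and green clones descending from a single
G2-X recombination event: a spatially coherent, isolated group of
single-labeled cells containing at least one cell of each color.  Groups
are formed by single-linkage proximity at a grouping radius (default
248 um, i.e. 82 px at the panorama pixel scale) and must lie at least an
isolation distance (default 200 um) from the nearest non-member
single-labeled cell.  Components spanning more than a flag diameter are
marked as possible mergers of overlapping clones rather than silently
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .simulate import UM_PER_PX


@dataclass(frozen=True)
class TwinSpotParams:
    group_radius: float = 82.0 * UM_PER_PX  # 248 um
    isolation_distance: float = 200.0
    overlap_flag_diameter: float | None = None  # default 2 * group_radius

    def __post_init__(self) -> None:
        if self.group_radius <= 0 or self.isolation_distance <= 0:
            raise ValueError("radii must be positive")
        if self.overlap_flag_diameter is not None and self.overlap_flag_diameter <= 0:
            raise ValueError("overlap_flag_diameter must be positive")

    @property
    def flag_diameter(self) -> float:
        return (self.overlap_flag_diameter
                if self.overlap_flag_diameter is not None
                else 2.0 * self.group_radius)


@dataclass
class TwinSpot:
    member_ids: list[int]
    n_red: int
    n_green: int
    centroid: tuple[float, float]
    diameter: float
    overlap_flagged: bool

    @property
    def size(self) -> int:
        return self.n_red + self.n_green

    @property
    def green_red_ratio(self) -> float:
        return self.n_green / self.n_red


def find_twin_spots(cells: pd.DataFrame,
                    params: TwinSpotParams | None = None) -> list[TwinSpot]:
    """Find twin spots among classified detections.

    ``cells`` needs columns id, x_um, y_um, class; yellow (double-labeled)
    cells are excluded from grouping.  Raises if any class is missing/NaN.
    """
    params = params or TwinSpotParams()
    if cells.empty:
        return []
    if cells["class"].isna().any():
        raise ValueError("all cells must be classified before twin-spot analysis")

    singles = cells[cells["class"].isin(["red", "green"])].reset_index(drop=True)
    if singles.empty:
        return []
    pts = singles[["x_um", "y_um"]].to_numpy(dtype=float)
    tree = cKDTree(pts)
    graph = tree.sparse_distance_matrix(tree, params.group_radius, output_type="coo_matrix")
    _, comp = connected_components(graph.tocsr(), directed=False)

    spots: list[TwinSpot] = []
    for label in np.unique(comp):
        members = np.flatnonzero(comp == label)
        classes = singles.loc[members, "class"]
        n_red = int((classes == "red").sum())
        n_green = int((classes == "green").sum())
        if n_red < 1 or n_green < 1:
            continue
        # isolation: every outside single-labeled cell farther than the
        # isolation distance from every member (automatic when the
        # isolation distance does not exceed the grouping radius)
        if params.isolation_distance > params.group_radius:
            outside = np.flatnonzero(comp != label)
            if outside.size:
                d, _ = cKDTree(pts[outside]).query(pts[members], k=1)
                if np.min(d) <= params.isolation_distance:
                    continue
        mpts = pts[members]
        diameter = float(pdist(mpts).max()) if len(mpts) > 1 else 0.0
        spots.append(TwinSpot(
            member_ids=singles.loc[members, "id"].tolist(),
            n_red=n_red,
            n_green=n_green,
            centroid=tuple(mpts.mean(axis=0)),
            diameter=diameter,
            overlap_flagged=diameter > params.flag_diameter,
        ))
    return spots


def twin_spot_stats(spots: list[TwinSpot], include_flagged: bool = True) -> dict:
    """Size histogram, fraction of 2-4-cell spots, and green/red ratios."""
    use = spots if include_flagged else [s for s in spots if not s.overlap_flagged]
    if not use:
        return {"n_spots": 0, "size_histogram": {}, "fraction_2_to_4": None,
                "per_spot_ratios": [], "pooled_green_red_ratio": None,
                "pooled_green_fraction": None}
    sizes = np.array([s.size for s in use])
    hist = {int(k): int(v) for k, v in zip(*np.unique(sizes, return_counts=True))}
    n_green = sum(s.n_green for s in use)
    n_red = sum(s.n_red for s in use)
    return {
        "n_spots": len(use),
        "size_histogram": hist,
        "fraction_2_to_4": float(np.mean((sizes >= 2) & (sizes <= 4))),
        "per_spot_ratios": [s.green_red_ratio for s in use],
        "pooled_green_red_ratio": n_green / n_red if n_red else None,
        "pooled_green_fraction": n_green / (n_green + n_red),
        "n_flagged": sum(s.overlap_flagged for s in spots),
    }


def spots_to_frame(spots: list[TwinSpot]) -> pd.DataFrame:
    """Twin spots as a tidy table (one row per spot)."""
    return pd.DataFrame([
        {"spot_id": i, "size": s.size, "n_red": s.n_red, "n_green": s.n_green,
         "centroid_x_um": s.centroid[0], "centroid_y_um": s.centroid[1],
         "diameter_um": s.diameter, "overlap_flagged": s.overlap_flagged}
        for i, s in enumerate(spots)])
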