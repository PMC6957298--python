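"""Junction-image segmentation and monolayer morphometry.

Cell outlines are recovered from a junction-label (ZO-1-like) boundary
image by a filter chain ending in a seeded Dirichlet partition: Gaussian
smoothing, seed extraction at regional minima of the junction signal
(h-minima with a depth parameter), and a watershed of the smoothed signal
from those seeds, which partitions the field into one polygon per cell
with boundaries constrained to the bright ridge lines.

Morphometric readouts follow standard endothelial morphometry: cell area
(um^2), circularity 4*pi*A/P^2, neighbor counts, and density in cells/mm^2
with border cells weighted one half.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import find_contours, perimeter_crofton
from skimage.morphology import h_minima
from skimage.segmentation import watershed

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationParams:
    smooth_sigma_um: float = 1.5
    h_depth_frac: float = 0.10      # h-minima depth, fraction of dynamic range
    min_cell_area_um2: float = 40.0


@dataclass
class CellTessellation:
    """Per-cell polygons and measurements from one boundary image.

    ``cells`` columns: id, centroid_x_um, centroid_y_um, area_um2,
    perimeter_um, is_border.  ``polygons`` maps id -> (n, 2) vertex array
    (um, x right / y down); ``neighbors`` maps id -> sorted neighbor ids.
    """

    cells: pd.DataFrame
    polygons: dict[int, np.ndarray]
    neighbors: dict[int, list[int]]
    pixel_scale: float
    source: str = ""
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def interior(self) -> pd.DataFrame:
        return self.cells[~self.cells["is_border"]]

    @classmethod
    def from_polygons(cls, polygons: list[np.ndarray], pixel_scale: float = 1.0,
                      is_border: list[bool] | None = None) -> "CellTessellation":
        """Build a tessellation from explicit polygons (vertices in um)."""
        from shapely.geometry import Polygon

        rows, polys, neigh = [], {}, {}
        shapes = [Polygon(p) for p in polygons]
        for i, sp in enumerate(shapes):
            polys[i] = np.asarray(polygons[i], dtype=float)
            rows.append({
                "id": i,
                "centroid_x_um": sp.centroid.x,
                "centroid_y_um": sp.centroid.y,
                "area_um2": sp.area,
                "perimeter_um": sp.length,
                "is_border": bool(is_border[i]) if is_border is not None else False,
            })
            # tolerant shared-edge test: vertex coordinates of adjacent
            # polygons may differ by floating-point rounding
            neigh[i] = sorted(
                j for j, so in enumerate(shapes)
                if j != i and
                sp.exterior.intersection(so.exterior.buffer(1e-3)).length > 1e-3)
        return cls(cells=pd.DataFrame(rows), polygons=polys, neighbors=neigh,
                   pixel_scale=pixel_scale)


def _label_adjacency(labels: np.ndarray, min_edge_px: int = 1) -> dict[int, set[int]]:
    """Neighbor relation between watershed labels sharing >= min_edge_px of
    4-connected boundary."""
    pairs = []
    for a, b in ((labels[:, :-1], labels[:, 1:]), (labels[:-1, :], labels[1:, :])):
        m = (a != b) & (a > 0) & (b > 0)
        if m.any():
            pairs.append(np.stack([a[m], b[m]], axis=1))
    adj: dict[int, set[int]] = {}
    if pairs:
        allp = np.vstack(pairs)
        allp.sort(axis=1)
        uniq, counts = np.unique(allp, axis=0, return_counts=True)
        for (i, j), c in zip(uniq, counts):
            if c >= min_edge_px:
                adj.setdefault(int(i), set()).add(int(j))
                adj.setdefault(int(j), set()).add(int(i))
    return adj


def detect_cells(image: np.ndarray, pixel_scale: float,
                 params: SegmentationParams | None = None,
                 origin_um: tuple[float, float] = (0.0, 0.0),
                 source: str = "") -> CellTessellation:
    """Segment cells from a junction-label image.

    Returns a tessellation in physical coordinates; cells touching the
    image border are flagged ``is_border``.
    """
    if pixel_scale is None or pixel_scale <= 0:
        raise ValueError("a positive pixel scale is required")
    params = params or SegmentationParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    rng_range = float(img.max() - img.min())
    empty = CellTessellation(
        cells=pd.DataFrame(columns=["id", "centroid_x_um", "centroid_y_um",
                                    "area_um2", "perimeter_um", "is_border"]),
        polygons={}, neighbors={}, pixel_scale=pixel_scale, source=source)
    if rng_range == 0:
        warnings.warn("constant-intensity image: no cells detected")
        return empty

    sigma_px = params.smooth_sigma_um / pixel_scale
    smooth = ndimage.gaussian_filter(img, sigma_px)
    # seeds: regional minima of the junction signal deeper than h
    h = params.h_depth_frac * float(smooth.max() - smooth.min())
    minima = h_minima(smooth, h)
    seeds, n_seeds = ndimage.label(minima)
    if n_seeds == 0:
        warnings.warn("no seeds found: no cells detected")
        return empty
    labels = watershed(smooth, markers=seeds)

    border_ids = set(np.unique(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])))
    adj = _label_adjacency(labels)

    rows = []
    polygons: dict[int, np.ndarray] = {}
    objects = ndimage.find_objects(labels)
    min_area_px = params.min_cell_area_um2 / pixel_scale ** 2
    dropped = []
    for lab_id in range(1, n_seeds + 1):
        sl = objects[lab_id - 1]
        if sl is None:
            continue
        mask = labels[sl] == lab_id
        area_px = int(mask.sum())
        if area_px < min_area_px:
            dropped.append(lab_id)
            continue
        per_px = perimeter_crofton(mask, directions=4)
        ys, xs = np.nonzero(mask)
        cy = (ys.mean() + sl[0].start) * pixel_scale + origin_um[1]
        cx = (xs.mean() + sl[1].start) * pixel_scale + origin_um[0]
        pad = np.pad(mask, 1)
        cont = find_contours(pad.astype(float), 0.5)
        if cont:
            c = max(cont, key=len)  # outer boundary
            verts = np.empty((len(c), 2))
            verts[:, 0] = (c[:, 1] - 1 + sl[1].start) * pixel_scale + origin_um[0]
            verts[:, 1] = (c[:, 0] - 1 + sl[0].start) * pixel_scale + origin_um[1]
            polygons[lab_id] = verts
        rows.append({
            "id": lab_id,
            "centroid_x_um": cx,
            "centroid_y_um": cy,
            "area_um2": area_px * pixel_scale ** 2,
            "perimeter_um": per_px * pixel_scale,
            "is_border": lab_id in border_ids,
        })
    if dropped:
        log.info("dropped %d degenerate/small segments", len(dropped))
    cells = pd.DataFrame(rows)
    keep = set(cells["id"]) if len(cells) else set()
    neighbors = {int(i): sorted(j for j in adj.get(int(i), ()) if j in keep)
                 for i in keep}
    return CellTessellation(cells=cells, polygons=polygons, neighbors=neighbors,
                            pixel_scale=pixel_scale, source=source,
                            meta={"n_seeds": int(n_seeds), "n_dropped": len(dropped)})


def circularity(area: np.ndarray, perimeter: np.ndarray) -> np.ndarray:
    """Shape regularity 4*pi*A/P^2, clipped to [0, 1] (1 = disc)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        c = 4.0 * np.pi * np.asarray(area, float) / np.asarray(perimeter, float) ** 2
    return np.clip(c, 0.0, 1.0)


def morphometrics(tess: CellTessellation) -> pd.DataFrame:
    """Per-cell area, circularity and neighbor count.

    Degenerate cells (area <= 0) are dropped with a log entry.  Border
    cells are retained in the table (flagged) but should be excluded from
    summary distributions; use ``tess.interior`` or the flag column.
    """
    if len(tess) == 0:
        raise ValueError("empty tessellation")
    cells = tess.cells.copy()
    bad = cells["area_um2"] <= 0
    if bad.any():
        log.info("dropping %d degenerate polygons", int(bad.sum()))
        cells = cells[~bad]
    cells["circularity"] = circularity(cells["area_um2"], cells["perimeter_um"])
    cells["n_neighbors"] = [len(tess.neighbors.get(int(i), ())) for i in cells["id"]]
    return cells.reset_index(drop=True)


def density(n_interior: int, area_mm2: float, n_border: int = 0) -> float:
    """Cell density in cells/mm^2; border cells count one half."""
    if area_mm2 <= 0:
        raise ValueError("sampled area must be positive")
    return (n_interior + 0.5 * n_border) / area_mm2


def tessellation_density(tess: CellTessellation, area_mm2: float) -> float:
    n_border = int(tess.cells["is_border"].sum())
    return density(len(tess) - n_border, area_mm2, n_border)


# ---------------------------------------------------------------------------
# regional sampling


@dataclass(frozen=True)
class RegionSpec:
    """Where the central and peripheral sampling sites live on the cornea."""

    center: tuple[float, float] = (0.0, 0.0)
    cornea_radius: float = 1500.0
    central_radius: float = 1250.0
    peripheral_band: float = 200.0
    n_quadrants: int = 4
    roi_size_um: float = 177.0  # ~0.031 mm^2 per site, 8 sites ~ 0.25 mm^2

    def __post_init__(self) -> None:
        if not (0 < self.central_radius < self.cornea_radius - self.peripheral_band):
            raise ValueError(
                "need 0 < central_radius < cornea_radius - peripheral_band")

    def classify(self, x: float, y: float) -> str:
        """Classify a point as 'central', 'peripheral' or 'excluded'."""
        r = float(np.hypot(x - self.center[0], y - self.center[1]))
        if r <= self.central_radius:
            return "central"
        if self.cornea_radius - self.peripheral_band < r <= self.cornea_radius:
            return "peripheral"
        return "excluded"


@dataclass(frozen=True)
class ROI:
    x_um: float  # top-left corner
    y_um: float
    size_um: float
    region: str   # central | peripheral
    quadrant: int


def sample_regions(spec: RegionSpec) -> list[ROI]:
    """One central and one peripheral square ROI per quadrant (8 total).

    Sites sit on the quadrant diagonals: central sites at half the central
    radius, peripheral sites centered in the peripheral band.  Per-class
    summaries should average the four fields of that class.
    """
    rois = []
    r_central = spec.central_radius / 2.0
    r_periph = spec.cornea_radius - spec.peripheral_band / 2.0
    # keep the whole ROI inside the rim
    r_periph = min(r_periph, spec.cornea_radius - spec.roi_size_um * np.sqrt(2) / 2)
    for q in range(spec.n_quadrants):
        theta = np.pi / 4 + q * (2 * np.pi / spec.n_quadrants)
        for region, r in (("central", r_central), ("peripheral", r_periph)):
            cx = spec.center[0] + r * np.cos(theta)
            cy = spec.center[1] + r * np.sin(theta)
            rois.append(ROI(x_um=cx - spec.roi_size_um / 2,
                            y_um=cy - spec.roi_size_um / 2,
                            size_um=spec.roi_size_um, region=region, quadrant=q))
    return rois
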