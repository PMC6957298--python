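"""Generative model of MADM-labeled corneal endothelial monolayers.

The corneal endothelium is a near-hexagonal monolayer of cells at roughly
1500-4000 cells/mm^2.  In a MADM (mosaic analysis with double markers)
cornea, rare Cre-mediated interchromosomal recombination events mark cells:

* G2-X segregation produces one red and one green sibling (in GR-MADM the
  green daughter is homozygous mutant, the red one homozygous wild type;
  in WT-MADM both are wild type),
* G2-Z segregation produces one yellow (double-labeled) and one colorless
  daughter, both heterozygous,
* G0/G1 recombination produces a single yellow cell.

Each single-labeled founder then expands into a clone and its progeny
disperse radially.  This module simulates that process on a disc-shaped
"cornea" and renders the result as two-channel fluorescence panoramas and
junction-label (ZO-1-like) boundary images so the whole quantification
pipeline can be exercised against known ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq
from scipy.spatial import Voronoi, cKDTree

#: physical pixel scale fixed by equating 82 px to 248 um.
UM_PER_PX = 248.0 / 82.0

GENERATOR_VERSION = "1.0"

COLOR_RED = "red"
COLOR_GREEN = "green"
COLOR_YELLOW = "yellow"
COLOR_NONE = "colorless"

GENOTYPE_WT = "WT"
GENOTYPE_MUT = "MUT"
GENOTYPE_HET = "HET"


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


class GeometryError(ValueError):
    """Raised when a rendering geometry is impossible (field too small etc.)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated MADM cornea.

    Lengths are in micrometers; densities in cells/mm^2.  ``expansion_fold``
    multiplies the baseline clone size per genotype (1 = wild-type
    expansion), so the expected clone size is ``base_clone_size *
    expansion_fold[genotype]`` and the expected green/red count ratio is the
    fold ratio.  ``dispersal_sigma`` is the isotropic per-division
    displacement scale of clone progeny.
    """

    cornea_radius: float = 1500.0
    target_density: float = 2500.0
    n_events: int = 20
    seg_probs: tuple[float, float, float] = (0.2, 0.2, 0.6)  # G2-X, G2-Z, G0/G1
    expansion_fold: dict[str, float] = field(
        default_factory=lambda: {GENOTYPE_WT: 1.0, GENOTYPE_MUT: 1.0, GENOTYPE_HET: 1.0}
    )
    base_clone_size: float = 1.7
    dispersal_sigma: dict[str, float] = field(
        default_factory=lambda: {GENOTYPE_WT: 20.0, GENOTYPE_MUT: 20.0, GENOTYPE_HET: 20.0}
    )
    mode: str = "WT-MADM"  # "WT-MADM" or "GR-MADM"
    pixel_scale: float = UM_PER_PX
    background_level: float = 100.0
    photon_noise: bool = True
    streak_artifacts: bool = False
    min_event_spacing: float | None = None
    lloyd_iterations: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cornea_radius <= 0:
            raise ConfigurationError("cornea_radius must be positive")
        if self.target_density <= 0:
            raise ConfigurationError("target_density must be positive")
        if self.pixel_scale <= 0:
            raise ConfigurationError("pixel_scale must be positive")
        if abs(sum(self.seg_probs) - 1.0) > 1e-9:
            raise ConfigurationError("seg_probs must sum to 1")
        if any(p < 0 for p in self.seg_probs):
            raise ConfigurationError("seg_probs must be non-negative")
        if any(f < 0 for f in self.expansion_fold.values()):
            raise ConfigurationError("expansion folds must be >= 0")
        if self.mode not in ("WT-MADM", "GR-MADM"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seg_probs"] = list(self.seg_probs)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


@dataclass
class SimulatedMonolayer:
    """Ground-truth cell table of one simulated cornea.

    ``cells`` has columns id, x_um, y_um, color, clone_id, event_id,
    genotype.  Background (unlabeled) cells carry color ``colorless`` and
    event_id/clone_id of -1.
    """

    cells: pd.DataFrame
    config: SimulationConfig
    provenance: dict = field(default_factory=dict)

    @property
    def labeled(self) -> pd.DataFrame:
        return self.cells[self.cells["color"] != COLOR_NONE]

    @property
    def single_labeled(self) -> pd.DataFrame:
        return self.cells[self.cells["color"].isin([COLOR_RED, COLOR_GREEN])]

    def counts(self) -> dict[str, int]:
        c = self.cells["color"].value_counts()
        return {k: int(c.get(k, 0)) for k in (COLOR_RED, COLOR_GREEN, COLOR_YELLOW)}


# ---------------------------------------------------------------------------
# geometry: blue-noise monolayer positions


def _bridson_disc(rng: np.random.Generator, radius: float, r_min: float,
                  k: int = 30) -> np.ndarray:
    """Bridson Poisson-disc sampling inside a disc of given radius.

    Returns (n, 2) coordinates centered on the origin with pairwise
    distances >= r_min.  Candidate rejection is vectorized over the k
    candidates of each active point.
    """
    cell = r_min / np.sqrt(2.0)
    half = radius + r_min
    n_grid = int(np.ceil(2 * half / cell))
    grid = -np.ones((n_grid, n_grid), dtype=np.int64)
    cap = int(1.1 * (0.7 / (r_min * r_min)) * (2 * half) ** 2) + 64
    pts = np.empty((cap, 2))
    n_pts = 0
    r2 = r_min * r_min

    def insert(p: np.ndarray) -> None:
        nonlocal n_pts
        pts[n_pts] = p
        grid[int((p[0] + half) / cell), int((p[1] + half) / cell)] = n_pts
        n_pts += 1

    insert(rng.uniform(-r_min, r_min, size=2))
    active = [0]
    # 11x11 grid window around the base covers every candidate's r_min ball
    w = 5
    while active:
        a = int(rng.integers(len(active)))
        base = pts[active[a]]
        theta = rng.uniform(0, 2 * np.pi, size=k)
        rad = rng.uniform(r_min, 2 * r_min, size=k)
        cand = base + np.stack([rad * np.cos(theta), rad * np.sin(theta)], axis=1)
        cand = cand[np.einsum("ij,ij->i", cand, cand) <= radius * radius]
        placed = False
        if len(cand):
            bi = int((base[0] + half) / cell)
            bj = int((base[1] + half) / cell)
            win = grid[max(bi - w, 0):bi + w + 1, max(bj - w, 0):bj + w + 1]
            nidx = win[win >= 0]
            if nidx.size:
                near = pts[nidx]
                d2 = ((cand[:, None, :] - near[None, :, :]) ** 2).sum(axis=2)
                ok = d2.min(axis=1) >= r2
            else:
                ok = np.ones(len(cand), dtype=bool)
            hit = np.flatnonzero(ok)
            if hit.size:
                insert(cand[hit[0]])
                active.append(n_pts - 1)
                placed = True
        if not placed:
            active[a] = active[-1]
            active.pop()
    return pts[:n_pts].copy()


def _lloyd_relax(points: np.ndarray, radius: float, iterations: int) -> np.ndarray:
    """Move points toward their Voronoi-cell centroids (clipped to the disc)."""
    from shapely.geometry import Point, Polygon

    disc = Point(0.0, 0.0).buffer(radius, quad_segs=64)
    pts = points.copy()
    for _ in range(iterations):
        vor = Voronoi(pts)
        new = pts.copy()
        for i, ridx in enumerate(vor.point_region):
            region = vor.regions[ridx]
            if not region:
                continue
            if -1 in region:
                continue  # unbounded: keep, it is outside or on the hull
            verts = vor.vertices[region]
            if np.all(np.hypot(verts[:, 0], verts[:, 1]) <= radius):
                # shoelace centroid, cheap path for interior cells
                x, y = verts[:, 0], verts[:, 1]
                xs, ys = np.roll(x, -1), np.roll(y, -1)
                cross = x * ys - xs * y
                area = cross.sum() / 2.0
                if abs(area) < 1e-12:
                    continue
                cx = ((x + xs) * cross).sum() / (6 * area)
                cy = ((y + ys) * cross).sum() / (6 * area)
                new[i] = (cx, cy)
            else:
                poly = Polygon(verts).intersection(disc)
                if not poly.is_empty and poly.area > 0:
                    new[i] = (poly.centroid.x, poly.centroid.y)
        r = np.hypot(new[:, 0], new[:, 1])
        out = r > radius
        if np.any(out):  # project strays back just inside the rim
            new[out] *= (radius * 0.999 / r[out])[:, None]
        pts = new
    return pts


# Bridson packings realize a density of ~0.63/r_min^2; choosing
# r_min = sqrt(0.55/density) overshoots the target count by ~15% so the
# packing can be thinned down to the exact count.
_BRIDSON_DENSITY_CONST = 0.55


def generate_positions(config: SimulationConfig) -> np.ndarray:
    """Blue-noise cell positions for one monolayer.

    Poisson-disc (Bridson) sampling in the cornea disc followed by a few
    Lloyd relaxation steps gives an epithelium-like, near-hexagonal packing.
    The sample is thinned to exactly ``round(density * area)`` points.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    density = config.target_density / 1e6  # cells per um^2
    area = np.pi * config.cornea_radius ** 2
    n_target = int(round(density * area))
    if n_target == 0:
        return np.empty((0, 2))
    r_min = np.sqrt(_BRIDSON_DENSITY_CONST / density)
    pts = _bridson_disc(rng, config.cornea_radius, r_min)
    while len(pts) < n_target:  # tiny fields can undershoot; tighten and retry
        r_min *= 0.9
        pts = _bridson_disc(rng, config.cornea_radius, r_min)
    if len(pts) > n_target:
        keep = rng.choice(len(pts), size=n_target, replace=False)
        pts = pts[np.sort(keep)]
    if len(pts) >= 4 and config.lloyd_iterations > 0:
        pts = _lloyd_relax(pts, config.cornea_radius, config.lloyd_iterations)
    return pts


def mean_cell_spacing(config: SimulationConfig) -> float:
    """Mean center-to-center spacing (um) of a hexagonal packing at the
    configured density."""
    density = config.target_density / 1e6
    return float(np.sqrt(2.0 / (np.sqrt(3.0) * density)))


# ---------------------------------------------------------------------------
# MADM event model


def _ztp_lambda(mean: float) -> float:
    """Rate of the zero-truncated Poisson with the given mean (>1)."""
    if mean <= 1.0 + 1e-12:
        return 0.0
    return brentq(lambda lam: lam / (1.0 - np.exp(-lam)) - mean, 1e-9, 10 * mean)


def _draw_clone_size(rng: np.random.Generator, mean: float) -> int:
    """Clone size with the exact expectation ``mean`` and minimum 1.

    Zero-truncated Poisson; mean <= 1 degenerates to a single cell.
    """
    lam = _ztp_lambda(mean)
    if lam == 0.0:
        return 1
    while True:
        n = rng.poisson(lam)
        if n > 0:
            return int(n)


def _disperse(rng: np.random.Generator, origin: np.ndarray, n: int,
              sigma: float, radius: float, min_sep: float,
              occupied: list[np.ndarray]) -> np.ndarray:
    """Positions of ``n`` clone members starting at ``origin``.

    Cells are bodies in a monolayer, not points: every placement keeps at
    least ``min_sep`` to every previously placed labeled cell
    (``occupied``, shared across the whole simulation).

    Two growth regimes follow from the dispersal scale.  When ``sigma`` is
    at least the contact distance, each cell takes one more cumulative
    isotropic Gaussian step along the lineage chain (migrating clone),
    reflected at the cornea rim.  When ``sigma`` is below the contact
    distance, progeny cannot out-run their own footprint, so the clone
    grows as a compact contact-packed clump around the founder.
    """
    pos = np.empty((n, 2))
    pos[0] = origin
    occupied.append(np.asarray(origin, float))

    def clip_rim(p: np.ndarray) -> np.ndarray:
        r = np.hypot(p[0], p[1])
        if r > radius:  # reflect across the rim
            p = p * ((2 * radius - r) / r)
            r = np.hypot(p[0], p[1])
            if r > radius:
                p = p * (radius * 0.999 / r)
        return p

    def clearance(c: np.ndarray) -> float:
        occ = np.asarray(occupied)
        return float(np.min(np.hypot(occ[:, 0] - c[0], occ[:, 1] - c[1])))

    def contact_pack(anchor_order: list[np.ndarray]) -> np.ndarray:
        """First free contact position around the clone, compact-first."""
        for m in anchor_order:
            for theta in rng.uniform(0.0, 2 * np.pi, size=16):
                c = clip_rim(m + min_sep * 1.001
                             * np.array([np.cos(theta), np.sin(theta)]))
                if clearance(c) >= min_sep:
                    return c
        # extremely crowded corner case: jittered push off the last member
        return clip_rim(anchor_order[0] + min_sep * rng.normal(size=2))

    clump_mode = sigma < min_sep
    cur = origin.astype(float).copy()
    members = [pos[0].copy()]
    for i in range(1, n):
        if clump_mode:
            order = sorted(members, key=lambda q: np.hypot(*(q - pos[0])))
            cand = contact_pack(order)
        else:
            for _ in range(50):
                cand = clip_rim(cur + rng.normal(0.0, sigma, size=2))
                if clearance(cand) >= min_sep:
                    break
            else:
                cand = contact_pack(sorted(members,
                                           key=lambda q: np.hypot(*(q - cur))))
            cur = cand
        pos[i] = cand
        members.append(np.asarray(cand, float))
        occupied.append(np.asarray(cand, float))
    return pos


def simulate_madm(config: SimulationConfig, positions: np.ndarray) -> SimulatedMonolayer:
    """Plant MADM recombination events on a monolayer and expand clones.

    Each event draws a segregation mode from ``config.seg_probs``:
    G2-X seeds adjacent red and green founders, G2-Z seeds one yellow and
    one colorless founder, G0/G1 a single yellow cell.  Single-labeled
    founders expand to clones with mean size
    ``base_clone_size * expansion_fold[genotype]``
    whose progeny take cumulative Gaussian steps of scale
    ``dispersal_sigma[genotype]``.  Remaining positions become unlabeled
    background cells.
    """
    if len(positions) == 0:
        raise ConfigurationError("positions must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_pos = len(positions)
    tree = cKDTree(positions)

    # event anchor positions: random distinct cells, optionally forced apart
    anchors: list[int] = []
    order = rng.permutation(n_pos)
    for idx in order:
        if len(anchors) >= config.n_events:
            break
        if config.min_event_spacing is not None and anchors:
            d = np.min(np.linalg.norm(positions[anchors] - positions[idx], axis=1))
            if d < config.min_event_spacing:
                continue
        anchors.append(int(idx))
    if len(anchors) < config.n_events:
        raise ConfigurationError(
            f"could not place {config.n_events} events "
            f"(placed {len(anchors)}; spacing constraint too tight?)")

    green_geno = GENOTYPE_MUT if config.mode == "GR-MADM" else GENOTYPE_WT
    spacing = mean_cell_spacing(config)
    records: list[tuple] = []
    occupied: list[np.ndarray] = []  # all labeled-cell positions so far
    used = np.zeros(n_pos, dtype=bool)
    clone_counter = 0
    radius = config.cornea_radius

    # first pass: draw segregation modes, pick founder positions, and
    # reserve every founder site before any clone disperses, so no clone
    # can wander onto another event's founder
    plans = []
    for event_id, anchor in enumerate(anchors):
        used[anchor] = True
        mode = int(rng.choice(3, p=config.seg_probs))
        origin = positions[anchor]
        sibling = None
        if mode in (0, 1):  # G2-X / G2-Z need an adjacent sibling position
            _, nearest = tree.query(origin, k=min(8, n_pos))
            sibling = next((int(j) for j in np.atleast_1d(nearest) if not used[j]),
                           None)
            if sibling is not None:
                used[sibling] = True
        plans.append((event_id, mode, origin, sibling))
        occupied.append(np.asarray(origin, float))
        if mode == 0 and sibling is not None:
            occupied.append(np.asarray(positions[sibling], float))

    # second pass: expand and disperse clones
    for event_id, mode, origin, sibling in plans:
        if mode == 0:  # G2-X: red + green sibling clones
            sib_pos = positions[sibling] if sibling is not None else origin
            for color, geno, start in (
                (COLOR_RED, GENOTYPE_WT, origin),
                (COLOR_GREEN, green_geno, sib_pos),
            ):
                size = _draw_clone_size(
                    rng, config.base_clone_size * config.expansion_fold.get(geno, 1.0))
                sigma = config.dispersal_sigma.get(geno, 0.0)
                pos = _disperse(rng, np.asarray(start, float), size, sigma, radius,
                                min_sep=0.75 * spacing, occupied=occupied)
                for p in pos:
                    records.append((p[0], p[1], color, clone_counter, event_id, geno))
                clone_counter += 1
        elif mode == 1:  # G2-Z: yellow + colorless heterozygous daughters
            records.append((origin[0], origin[1], COLOR_YELLOW, clone_counter,
                            event_id, GENOTYPE_HET))
            clone_counter += 1
            if sibling is not None:
                sp = positions[sibling]
                records.append((sp[0], sp[1], COLOR_NONE, clone_counter,
                                event_id, GENOTYPE_HET))
                clone_counter += 1
        else:  # G0/G1: single yellow cell
            records.append((origin[0], origin[1], COLOR_YELLOW, clone_counter,
                            event_id, GENOTYPE_HET))
            clone_counter += 1

    # unlabeled background fills the remaining lattice positions
    for idx in np.flatnonzero(~used):
        records.append((positions[idx][0], positions[idx][1], COLOR_NONE,
                        -1, -1, GENOTYPE_WT))

    cells = pd.DataFrame(records,
                         columns=["x_um", "y_um", "color", "clone_id",
                                  "event_id", "genotype"])
    # background colorless rows keep event_id -1
    cells.loc[cells["clone_id"] == -1, "event_id"] = -1
    cells.insert(0, "id", np.arange(len(cells)))
    return SimulatedMonolayer(
        cells=cells,
        config=config,
        provenance={"seed": config.seed, "generator_version": GENERATOR_VERSION},
    )


# ---------------------------------------------------------------------------
# rendering


def _field_shape(config: SimulationConfig, margin_um: float = 30.0) -> tuple[int, float]:
    """Square image side (px) and half-extent (um) covering the cornea disc."""
    half = config.cornea_radius + margin_um
    side = int(np.ceil(2 * half / config.pixel_scale)) + 1
    return side, half


def _stamp_spots(img: np.ndarray, cols: np.ndarray, rows: np.ndarray,
                 amplitude: float, sigma_px: float) -> None:
    """Add Gaussian spots in place (vectorized per-spot patch stamping)."""
    r = int(np.ceil(4 * sigma_px))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    h, w = img.shape
    for c, ro in zip(cols, rows):
        ci, ri = int(round(c)), int(round(ro))
        kern = amplitude * np.exp(-(((xx + ci - c) ** 2) + ((yy + ri - ro) ** 2))
                                  / (2 * sigma_px ** 2))
        i0, i1 = max(ri - r, 0), min(ri + r + 1, h)
        j0, j1 = max(ci - r, 0), min(ci + r + 1, w)
        img[i0:i1, j0:j1] += kern[(i0 - ri + r):(i1 - ri + r),
                                  (j0 - ci + r):(j1 - ci + r)]


def render_channels(monolayer: SimulatedMonolayer,
                    config: SimulationConfig | None = None,
                    spot_sigma_um: float = 4.0,
                    amplitude: float = 3000.0,
                    field_um: float | None = None) -> tuple[np.ndarray, float]:
    """Render a two-channel (red, green) panorama of the labeled cells.

    Red cells appear in channel 0, green in channel 1, yellow in both.
    Returns a (2, H, W) uint16 stack and its pixel scale (um/px).  The
    cornea center maps to the image center; a cell at physical (x, y)
    produces a spot maximum at pixel (col, row) = round((x, y)+half)/scale.
    """
    config = config or monolayer.config
    if config.pixel_scale <= 0:
        raise GeometryError("pixel_scale must be positive")
    side, half = _field_shape(config)
    if field_um is not None:
        if field_um < 2 * config.cornea_radius:
            raise GeometryError("field too small to contain the cornea disc")
        side = int(np.ceil(field_um / config.pixel_scale)) + 1
        half = field_um / 2.0
    scale = config.pixel_scale
    sigma_px = spot_sigma_um / scale
    img = np.zeros((2, side, side), dtype=float)

    cells = monolayer.cells
    for chan, colors in ((0, (COLOR_RED, COLOR_YELLOW)),
                         (1, (COLOR_GREEN, COLOR_YELLOW))):
        sub = cells[cells["color"].isin(colors)]
        cols = (sub["x_um"].to_numpy() + half) / scale
        rows = (sub["y_um"].to_numpy() + half) / scale
        _stamp_spots(img[chan], cols, rows, amplitude, sigma_px)

    img += config.background_level
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    if config.streak_artifacts:
        img[1] += _epithelial_streaks(rng, side, scale, config.cornea_radius,
                                      amplitude * 0.4)
    if config.photon_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    return np.clip(img, 0, 65535).astype(np.uint16), scale


def _epithelial_streaks(rng: np.random.Generator, side: int, scale: float,
                        radius: float, amplitude: float,
                        n_streaks: int = 6) -> np.ndarray:
    """Green radial streaks emulating bleed-through from the epithelium."""
    from skimage.draw import line_aa

    canvas = np.zeros((side, side), dtype=float)
    center = side / 2.0
    r_px = radius / scale
    for _ in range(n_streaks):
        theta = rng.uniform(0, 2 * np.pi)
        r0 = rng.uniform(0.2, 0.5) * r_px
        r1 = rng.uniform(0.7, 0.98) * r_px
        p0 = (int(center + r0 * np.sin(theta)), int(center + r0 * np.cos(theta)))
        p1 = (int(center + r1 * np.sin(theta)), int(center + r1 * np.cos(theta)))
        rr, cc, val = line_aa(*p0, *p1)
        ok = (rr >= 0) & (rr < side) & (cc >= 0) & (cc < side)
        canvas[rr[ok], cc[ok]] += val[ok] * amplitude
    # widen the streaks along their length
    return ndimage.gaussian_filter(canvas, sigma=2.0 / scale * 3)


def render_junctions(positions: np.ndarray, config: SimulationConfig,
                     ridge_sigma_um: float = 1.5,
                     amplitude: float = 3000.0) -> tuple[np.ndarray, float]:
    """Render a junction-label (boundary) image of the monolayer.

    Bright ridges run along the Dirichlet-tessellation edges of the cell
    positions; interiors stay dark.  Returns (H, W) uint16 and the pixel
    scale.
    """
    from skimage.draw import line_aa

    if len(positions) < 3:
        raise GeometryError("need at least 3 positions to tessellate")
    scale = config.pixel_scale
    side, half = _field_shape(config)
    canvas = np.zeros((side, side), dtype=float)
    vor = Voronoi(positions)
    center = positions.mean(axis=0)
    far = 4.0 * half  # long enough to leave the rendered field
    segments = []
    for pointidx, (v0, v1) in zip(vor.ridge_points, vor.ridge_vertices):
        if v0 >= 0 and v1 >= 0:
            segments.append((vor.vertices[v0], vor.vertices[v1]))
        else:  # unbounded ridge: extend from the finite vertex outward
            vfin = vor.vertices[v1 if v0 < 0 else v0]
            t = positions[pointidx[1]] - positions[pointidx[0]]
            t = t / np.hypot(*t)
            normal = np.array([-t[1], t[0]])
            midpoint = positions[pointidx].mean(axis=0)
            direction = np.sign(np.dot(midpoint - center, normal)) * normal
            segments.append((vfin, vfin + direction * far))
    lim = 8.0 * half  # drop degenerate, extremely distant vertices
    for a, b in segments:
        if max(abs(a).max(), abs(b).max()) > lim:
            continue
        r0, c0 = int(round((a[1] + half) / scale)), int(round((a[0] + half) / scale))
        r1, c1 = int(round((b[1] + half) / scale)), int(round((b[0] + half) / scale))
        # clip endpoints into the canvas frame before rasterizing
        r0, r1 = np.clip([r0, r1], -4 * side, 4 * side)
        c0, c1 = np.clip([c0, c1], -4 * side, 4 * side)
        rr, cc, val = line_aa(int(r0), int(c0), int(r1), int(c1))
        ok = (rr >= 0) & (rr < side) & (cc >= 0) & (cc < side)
        canvas[rr[ok], cc[ok]] = np.maximum(canvas[rr[ok], cc[ok]], val[ok])
    canvas = ndimage.gaussian_filter(canvas, sigma=ridge_sigma_um / scale)
    if canvas.max() > 0:
        canvas *= amplitude / canvas.max()
    canvas += config.background_level
    if config.photon_noise:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
        canvas = rng.poisson(np.clip(canvas, 0, None)).astype(float)
    return np.clip(canvas, 0, 65535).astype(np.uint16), scale


# ---------------------------------------------------------------------------
# presets emulating the three study genotype modes


def preset_config(name: str, **overrides) -> SimulationConfig:
    """Study-condition presets.

    ``WT``  : WT-MADM, symmetric 1x expansion, moderate dispersal.
    ``CK``  : GR-MADM with ~3x mutant expansion and strong scattering
              (cyclin/CDK-binding-dead allele phenotype).
    ``KO``  : GR-MADM with ~6x mutant expansion and tight clustering
              (null allele phenotype).
    """
    presets = {
        "WT": dict(
            mode="WT-MADM",
            expansion_fold={GENOTYPE_WT: 1.0, GENOTYPE_MUT: 1.0, GENOTYPE_HET: 1.0},
            dispersal_sigma={GENOTYPE_WT: 20.0, GENOTYPE_MUT: 20.0, GENOTYPE_HET: 20.0},
        ),
        "CK": dict(
            mode="GR-MADM",
            expansion_fold={GENOTYPE_WT: 1.0, GENOTYPE_MUT: 3.0, GENOTYPE_HET: 1.0},
            dispersal_sigma={GENOTYPE_WT: 400.0, GENOTYPE_MUT: 400.0, GENOTYPE_HET: 20.0},
        ),
        "KO": dict(
            mode="GR-MADM",
            expansion_fold={GENOTYPE_WT: 1.0, GENOTYPE_MUT: 6.0, GENOTYPE_HET: 1.0},
            dispersal_sigma={GENOTYPE_WT: 20.0, GENOTYPE_MUT: 8.0, GENOTYPE_HET: 20.0},
        ),
    }
    if name not in presets:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    kwargs = dict(presets[name])
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
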