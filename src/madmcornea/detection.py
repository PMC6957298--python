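"""Detection and color classification of MADM-labeled cells.

Input is a registered two-channel (red, green) panorama of the endothelial
monolayer.  Each channel is band-pass filtered (difference of Gaussians at
the cell-spot scale) and local maxima above a robust background threshold
become candidate cells.  Candidates from the two channels lying within a
pairing radius are merged into a single detection; every detection carries
both channel intensities and is classified red / green / yellow by
per-channel thresholds.

Flat-mounted corneas occasionally fold so that fluorescent epithelial
cells bleed into the green channel as long radial streaks; a connected-
component elongation filter removes such structures before peak picking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label, regionprops


@dataclass(frozen=True)
class DetectionParams:
    spot_sigma_um: float = 4.0          # band-pass center scale
    pairing_radius_um: float = 5.0      # cross-channel merge radius
    min_separation_um: float = 8.0      # duplicate suppression radius
    snr_threshold: float = 6.0          # peak height over robust background noise
    streak_aspect_ratio: float = 5.0    # reject elongated components above this
    streak_min_length_um: float = 100.0


@dataclass
class LabeledCellSet:
    """Classified detections with per-channel intensities (background
    subtracted), physical coordinates in um and the source pixel scale."""

    detections: pd.DataFrame  # id, x_um, y_um, red_int, green_int, class
    pixel_scale: float
    source: str = ""
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.detections)

    def points(self, classes: tuple[str, ...] = ("red", "green", "yellow")) -> np.ndarray:
        sub = self.detections[self.detections["class"].isin(classes)]
        return sub[["x_um", "y_um"]].to_numpy(dtype=float)

    def counts(self) -> dict[str, int]:
        c = self.detections["class"].value_counts()
        return {k: int(c.get(k, 0)) for k in ("red", "green", "yellow")}


def classify_color(red_int: float, green_int: float,
                   red_threshold: float, green_threshold: float) -> str:
    """Classify one detection from its channel intensities.

    Both channels above threshold -> yellow (double-labeled); exactly one
    above -> that color; neither -> "none".
    """
    if red_int < 0 or green_int < 0:
        raise ValueError("intensities must be non-negative")
    r = red_int > red_threshold
    g = green_int > green_threshold
    if r and g:
        return "yellow"
    if r:
        return "red"
    if g:
        return "green"
    return "none"


def _suppress_streaks(chan: np.ndarray, params: DetectionParams,
                      scale: float) -> tuple[np.ndarray, int]:
    """Zero out elongated bright components (epithelial bleed-through)."""
    bg = np.median(chan)
    noise = 1.4826 * np.median(np.abs(chan - bg)) + 1e-9
    mask = chan > bg + 4.0 * noise
    lab = cc_label(mask)
    cleaned = chan.copy()
    removed = 0
    min_len_px = params.streak_min_length_um / scale
    for rp in regionprops(lab):
        if rp.axis_major_length < min_len_px:
            continue
        minor = max(rp.axis_minor_length, 1.0)
        if rp.axis_major_length / minor > params.streak_aspect_ratio:
            sl = lab[rp.slice] == rp.label
            cleaned[rp.slice][sl] = bg
            removed += 1
    return cleaned, removed


def _bandpass(chan: np.ndarray, sigma_px: float) -> np.ndarray:
    # wide background sigma keeps the negative surround shallow, so cells
    # in the interior of a contact-packed clump keep their local maxima
    lo = ndimage.gaussian_filter(chan, sigma_px)
    hi = ndimage.gaussian_filter(chan, 6.0 * sigma_px)
    return lo - hi


def _channel_peaks(chan: np.ndarray, params: DetectionParams,
                   scale: float) -> np.ndarray:
    sigma_px = params.spot_sigma_um / scale
    dog = _bandpass(chan, sigma_px)
    noise = 1.4826 * np.median(np.abs(dog - np.median(dog))) + 1e-9
    thr = np.median(dog) + params.snr_threshold * noise
    min_dist = max(int(round(params.min_separation_um / scale)), 1)
    return peak_local_max(dog, min_distance=min_dist, threshold_abs=thr,
                          exclude_border=False)


def _spot_intensity(chan_smooth: np.ndarray, rows: np.ndarray,
                    cols: np.ndarray) -> np.ndarray:
    bg = np.median(chan_smooth)
    return np.clip(chan_smooth[rows, cols] - bg, 0.0, None)


def _merge_within(points_px: np.ndarray, radius_px: float) -> np.ndarray:
    """Average-merge points closer than radius (single linkage)."""
    if len(points_px) == 0:
        return points_px
    from scipy.sparse.csgraph import connected_components

    tree = cKDTree(points_px)
    g = tree.sparse_distance_matrix(tree, radius_px, output_type="coo_matrix")
    _, comp = connected_components(g.tocsr(), directed=False)
    out = np.empty((comp.max() + 1, points_px.shape[1]))
    for k in range(comp.max() + 1):
        out[k] = points_px[comp == k].mean(axis=0)
    return out


def detect_labeled_cells(image: np.ndarray, pixel_scale: float,
                         params: DetectionParams | None = None,
                         origin_um: tuple[float, float] = (0.0, 0.0),
                         source: str = "") -> LabeledCellSet:
    """Detect and classify labeled cells in a (2, H, W) red/green panorama.

    ``origin_um`` gives the physical coordinate of pixel (0, 0) so that
    detections can be reported in the cornea-centered frame.
    """
    params = params or DetectionParams()
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[0] != 2:
        raise ValueError("expected a (2, H, W) two-channel image")
    red, green = image[0], image[1]
    if red.shape != green.shape:
        raise ValueError("channel shapes differ")
    meta: dict = {}
    if np.any(image >= 65535):
        meta["saturation_warning"] = True

    green_clean, n_removed = _suppress_streaks(green, params, pixel_scale)
    meta["streaks_removed"] = n_removed

    peaks = [_channel_peaks(red, params, pixel_scale),
             _channel_peaks(green_clean, params, pixel_scale)]
    all_peaks = np.vstack([p for p in peaks if len(p)]) if any(len(p) for p in peaks) \
        else np.empty((0, 2))
    merged = _merge_within(all_peaks.astype(float), params.pairing_radius_um / pixel_scale)

    if len(merged) == 0:
        det = pd.DataFrame(columns=["id", "x_um", "y_um", "red_int", "green_int", "class"])
        return LabeledCellSet(detections=det, pixel_scale=pixel_scale,
                              source=source, meta=meta)

    rows = np.clip(np.round(merged[:, 0]).astype(int), 0, red.shape[0] - 1)
    cols = np.clip(np.round(merged[:, 1]).astype(int), 0, red.shape[1] - 1)
    sigma_px = params.spot_sigma_um / pixel_scale
    red_s = ndimage.gaussian_filter(red, sigma_px / 2.0)
    green_s = ndimage.gaussian_filter(green_clean, sigma_px / 2.0)
    red_int = _spot_intensity(red_s, rows, cols)
    green_int = _spot_intensity(green_s, rows, cols)

    red_thr, green_thr = channel_thresholds(
        red_s, green_s, params,
        spot_intensities=np.concatenate([red_int, green_int]))
    classes = [classify_color(r, g, red_thr, green_thr)
               for r, g in zip(red_int, green_int)]

    det = pd.DataFrame({
        "id": np.arange(len(merged)),
        "x_um": origin_um[0] + cols * pixel_scale,
        "y_um": origin_um[1] + rows * pixel_scale,
        "red_int": red_int,
        "green_int": green_int,
        "class": classes,
    })
    det = det[det["class"] != "none"].reset_index(drop=True)
    det["id"] = np.arange(len(det))
    meta["thresholds"] = {"red": float(red_thr), "green": float(green_thr)}
    return LabeledCellSet(detections=det, pixel_scale=pixel_scale,
                          source=source, meta=meta)


def channel_thresholds(red_smooth: np.ndarray, green_smooth: np.ndarray,
                       params: DetectionParams,
                       spot_intensities: np.ndarray | None = None
                       ) -> tuple[float, float]:
    """Per-channel intensity thresholds for color calling.

    A spot counts as positive in a channel when its background-subtracted
    intensity clears a robust noise floor (MAD-based sigma of the smoothed
    channel times the SNR setting) and a relative floor of 5% of the
    brightest detected spot (which suppresses Gaussian-tail residuals on
    noiseless images).  Both floors scale with the image, so classification
    is invariant under a simultaneous rescaling of both channels.  (Otsu's
    threshold over spot intensities — the obvious alternative — splits a
    unimodal channel, e.g. an image with no green cells, into a spurious
    positive class.)
    """
    rel_floor = 0.0
    if spot_intensities is not None and spot_intensities.size:
        rel_floor = 0.05 * float(np.max(spot_intensities))
    out = []
    for chan in (red_smooth, green_smooth):
        med = float(np.median(chan))
        noise = 1.4826 * float(np.median(np.abs(chan - med))) + 1e-9
        out.append(max(params.snr_threshold * noise, rel_floor))
    return out[0], out[1]
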