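"""Per-cornea quantification reports and batch aggregation.

The headline readout of a mosaic cornea is the green/red cell ratio —
the count of green single-labeled cells over the count of red ones, a
proxy for mutant-versus-wild-type clonal expansion — together with
regional densities, morphometry summaries, twin-spot and cluster
summaries.  Batch mode stacks per-cornea reports into a tidy long table
(one row per cornea x metric) and reports means +/- SEM per genotype
group, the layout downstream inferential statistics consume.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .__about__ import __version__
from .detection import LabeledCellSet


@dataclass
class CorneaReport:
    cornea_id: str
    mode: str  # WT-MADM | GR-MADM-CK | GR-MADM-KO | unspecified
    counts: dict[str, int] = field(default_factory=dict)
    green_red_ratio: float | None = None
    ratio_undefined: bool = False
    densities: dict[str, float | None] = field(default_factory=dict)
    morphometry: dict = field(default_factory=dict)
    twin_spots: dict = field(default_factory=dict)
    clusters: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    software_version: str = ""
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def green_red_ratio(cells: LabeledCellSet | pd.DataFrame) -> tuple[float | None, dict[str, int]]:
    """Green/red single-labeled cell ratio.

    Returns (ratio, counts); the ratio is None (undefined) when there are
    no red cells, with the counts still reported.
    """
    det = cells.detections if isinstance(cells, LabeledCellSet) else cells
    c = det["class"].value_counts()
    counts = {k: int(c.get(k, 0)) for k in ("red", "green", "yellow")}
    if counts["red"] == 0:
        return None, counts
    return counts["green"] / counts["red"], counts


def fold_change(mutant: float, control: float) -> tuple[float, float]:
    """(fold, percent change) of a metric relative to control."""
    if control <= 0:
        raise ValueError("control metric must be positive")
    fold = mutant / control
    return fold, 100.0 * (mutant - control) / control


def summarize_cornea(cornea_id: str,
                     detections: LabeledCellSet | None = None,
                     morphometry: pd.DataFrame | None = None,
                     regional_densities: dict[str, float] | None = None,
                     twin_spot_summary: dict | None = None,
                     cluster_summary: dict | None = None,
                     mode: str = "unspecified",
                     parameters: dict | None = None,
                     seed: int | None = None) -> CorneaReport:
    """Assemble one validated report; missing stages become explicit nulls."""
    report = CorneaReport(cornea_id=cornea_id, mode=mode,
                          parameters=parameters or {},
                          software_version=__version__, seed=seed)
    if detections is not None:
        ratio, counts = green_red_ratio(detections)
        report.counts = counts
        report.green_red_ratio = ratio
        report.ratio_undefined = ratio is None
    if morphometry is not None and len(morphometry):
        interior = morphometry[~morphometry["is_border"]] \
            if "is_border" in morphometry else morphometry
        hist = interior["n_neighbors"].value_counts().sort_index() \
            if "n_neighbors" in interior else pd.Series(dtype=int)
        report.morphometry = {
            "n_cells": int(len(interior)),
            "mean_area_um2": float(interior["area_um2"].mean()),
            "mean_circularity": float(interior["circularity"].mean())
            if "circularity" in interior else None,
            "neighbor_histogram": {int(k): int(v) for k, v in hist.items()},
        }
    report.densities = dict(regional_densities or {"central": None, "peripheral": None})
    report.twin_spots = twin_spot_summary or {}
    report.clusters = cluster_summary or {}
    return report


def batch_summary(reports: list[CorneaReport]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy long table (cornea x metric) plus mean +/- SEM per mode group."""
    rows = []
    for r in reports:
        metrics: dict[str, float | None] = {
            "n_red": r.counts.get("red"),
            "n_green": r.counts.get("green"),
            "n_yellow": r.counts.get("yellow"),
            "green_red_ratio": r.green_red_ratio,
            "density_central": r.densities.get("central"),
            "density_peripheral": r.densities.get("peripheral"),
            "mean_area_um2": r.morphometry.get("mean_area_um2"),
            "mean_circularity": r.morphometry.get("mean_circularity"),
            "n_twin_spots": r.twin_spots.get("n_spots"),
            "twin_spot_fraction_2_to_4": r.twin_spots.get("fraction_2_to_4"),
        }
        for color, stats in (r.clusters.get("per_color") or {}).items():
            metrics[f"percent_in_clusters_{color}"] = stats.get("percent_in_clusters")
        for metric, value in metrics.items():
            if value is not None:
                rows.append({"cornea_id": r.cornea_id, "mode": r.mode,
                             "metric": metric, "value": float(value)})
    long = pd.DataFrame(rows, columns=["cornea_id", "mode", "metric", "value"])
    if long.empty:
        return long, pd.DataFrame(columns=["mode", "metric", "mean", "sem", "n"])
    grp = long.groupby(["mode", "metric"])["value"]
    summary = grp.agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v))
                      if len(v) > 1 else 0.0, n="count").reset_index()
    return long, summary
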