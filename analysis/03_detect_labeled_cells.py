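"""Detect and classify labeled cells in the simulated cohort panoramas.

Reads the configs written by 01_simulate_cohort.py, re-renders each
cornea's two-channel panorama, runs spot detection + color classification,
and reports per-cornea detection accuracy against the generator's truth
table.  Writes detections CSVs and an accuracy summary.
"""

import json
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from madmcornea import (SimulationConfig, detect_labeled_cells,
                        generate_positions, io, render_channels, simulate_madm)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def match_detections(gt, det, radius_um=10.0):
    """Greedy class-aware matching; returns the number of true positives."""
    if len(det) == 0:
        return 0
    tree = cKDTree(det[["x_um", "y_um"]].to_numpy())
    tp = 0
    used = set()
    for _, row in gt.iterrows():
        d, i = tree.query([row.x_um, row.y_um], k=min(3, len(det)))
        for dd, ii in zip(np.atleast_1d(d), np.atleast_1d(i)):
            if dd < radius_um and int(ii) not in used \
                    and det["class"].iloc[int(ii)] == row.color:
                tp += 1
                used.add(int(ii))
                break
    return tp


def geometry_config(cfg: SimulationConfig, cid: str) -> SimulationConfig:
    """Both eyes of an animal share the monolayer geometry (see 01)."""
    animal = int(cid.split("-a")[1][0])
    seed_base = (cfg.seed // 1000) * 100 + animal
    return SimulationConfig(**{**cfg.to_dict(), "seed": seed_base})


def main() -> None:
    cohort = RESULTS / "cohort"
    if not cohort.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    summary = {}
    for cfg_path in sorted(cohort.glob("*_config.yaml")):
        cid = cfg_path.name.replace("_config.yaml", "")
        cfg = io.read_config(cfg_path)
        positions = generate_positions(geometry_config(cfg, cid))
        mono = simulate_madm(cfg, positions)
        img, scale = render_channels(mono)
        half = cfg.cornea_radius + 30.0
        cells = detect_labeled_cells(img, scale, origin_um=(-half, -half))
        cells.detections.to_csv(cohort / f"{cid}_detections.csv", index=False)
        tp = match_detections(mono.labeled, cells.detections)
        summary[cid] = {
            "ground_truth": len(mono.labeled),
            "detections": len(cells),
            "recall": round(tp / len(mono.labeled), 4),
            "precision": round(tp / len(cells), 4) if len(cells) else None,
        }
        print(cid, summary[cid])
    (cohort / "detection_summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
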