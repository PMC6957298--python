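"""Assemble per-cornea reports and the cohort-level summary table.

Combines detections, twin-spot and cluster outputs into one validated
report per cornea, then writes the tidy long-format table (one row per
cornea x metric) and per-genotype means +/- SEM — the green/red ratio per
genotype is the headline column.
"""

import json
from pathlib import Path

from madmcornea import (LabeledCellSet, batch_summary, find_twin_spots, io,
                        summarize_cornea, twin_spot_stats)
from madmcornea.clustering import cluster_cells

RESULTS = Path(__file__).resolve().parents[1] / "results"
MODES = {"WT": "WT-MADM", "CK": "GR-MADM-CK", "KO": "GR-MADM-KO"}


def main() -> None:
    cohort = RESULTS / "cohort"
    det_paths = sorted(cohort.glob("*_detections.csv"))
    if not det_paths:
        raise SystemExit("run analysis/03_detect_labeled_cells.py first")
    reports = []
    for path in det_paths:
        cid = path.name.replace("_detections.csv", "")
        preset = cid.split("-")[0]
        det = io.read_detections(path)
        cells = LabeledCellSet(detections=det, pixel_scale=io.read_config(
            cohort / f"{cid}_config.yaml").pixel_scale)
        spots = find_twin_spots(det)
        _, cluster_summary = cluster_cells(det)
        rep = summarize_cornea(cid, detections=cells,
                               twin_spot_summary=twin_spot_stats(spots),
                               cluster_summary=cluster_summary,
                               mode=MODES[preset])
        (cohort / f"{cid}_report.json").write_text(rep.to_json())
        reports.append(rep)

    long, summary = batch_summary(reports)
    long.to_csv(RESULTS / "cohort_long.csv", index=False)
    summary.to_csv(RESULTS / "cohort_summary.csv", index=False)
    ratios = summary[summary.metric == "green_red_ratio"]
    print(ratios.to_string(index=False))
    print(f"-> {RESULTS/'cohort_summary.csv'}")


if __name__ == "__main__":
    main()
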