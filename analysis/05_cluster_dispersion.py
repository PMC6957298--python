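"""Density-based dispersion analysis of the simulated cohort.

Clusters each cornea's single-labeled cells per color (eps = 136 um,
minimum density 4) and summarizes percent-in-cluster per genotype — the
dispersion readout that separates scattering (CK-like) from tightly
clustering (KO-like) mutant cells.
"""

import json
from collections import defaultdict
from pathlib import Path

import numpy as np

from madmcornea import io
from madmcornea.clustering import cluster_cells

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = RESULTS / "cohort"
    det_paths = sorted(cohort.glob("*_detections.csv"))
    if not det_paths:
        raise SystemExit("run analysis/03_detect_labeled_cells.py first")
    per_preset = defaultdict(lambda: defaultdict(list))
    for path in det_paths:
        cid = path.name.replace("_detections.csv", "")
        preset = cid.split("-")[0]
        det = io.read_detections(path)
        assigned, summary = cluster_cells(det)
        assigned.to_csv(cohort / f"{cid}_clusters.csv", index=False)
        for color, stats in summary["per_color"].items():
            if stats["percent_in_clusters"] is not None:
                per_preset[preset][color].append(stats["percent_in_clusters"])

    out = {}
    for preset, colors in per_preset.items():
        out[preset] = {
            color: {"mean_percent_in_clusters": round(float(np.mean(v)), 1),
                    "n_corneas": len(v)}
            for color, v in colors.items()}
        print(preset, out[preset])
    (RESULTS / "dispersion_summary.json").write_text(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
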