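"""Reading and writing of pipeline artifacts.

Images travel as TIFF (uint16, pixel scale recorded in the ImageDescription
as JSON), tables as CSV, configurations as YAML/JSON, reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .segmentation import CellTessellation
from .simulate import SimulatedMonolayer, SimulationConfig


def write_tiff(path: str | Path, image: np.ndarray, pixel_scale: float,
               origin_um: tuple[float, float] = (0.0, 0.0)) -> None:
    """Write a uint16 TIFF with pixel-scale metadata (um/px)."""
    desc = json.dumps({"pixel_scale_um": pixel_scale,
                       "origin_um": list(origin_um)})
    tifffile.imwrite(path, np.asarray(image, dtype=np.uint16), description=desc)


def read_tiff(path: str | Path) -> tuple[np.ndarray, float | None, tuple[float, float]]:
    """Read a TIFF; returns (image, pixel_scale or None, origin)."""
    with tifffile.TiffFile(path) as tf:
        img = tf.asarray()
        desc = tf.pages[0].description
    scale, origin = None, (0.0, 0.0)
    if desc:
        try:
            meta = json.loads(desc)
            scale = meta.get("pixel_scale_um")
            origin = tuple(meta.get("origin_um", origin))
        except (json.JSONDecodeError, AttributeError):
            pass
    return img, scale, origin


def write_cell_table(path: str | Path, monolayer: SimulatedMonolayer) -> None:
    monolayer.cells.to_csv(path, index=False)


def write_config(path: str | Path, config: SimulationConfig) -> None:
    path = Path(path)
    d = config.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=True))
    else:
        path.write_text(json.dumps(d, indent=2, sort_keys=True))


def read_config(path: str | Path) -> SimulationConfig:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    if "seg_probs" in d:
        d["seg_probs"] = tuple(d["seg_probs"])
    return SimulationConfig(**d)


def write_tessellation(path_csv: str | Path, tess: CellTessellation,
                       path_polygons: str | Path | None = None) -> None:
    """Cell table as CSV plus optional polygon vertex lists as JSON."""
    from .segmentation import morphometrics

    table = morphometrics(tess) if len(tess) else tess.cells
    table.to_csv(path_csv, index=False)
    if path_polygons is not None:
        payload = {str(i): v.tolist() for i, v in tess.polygons.items()}
        Path(path_polygons).write_text(json.dumps(payload))


def read_detections(path: str | Path) -> pd.DataFrame:
    det = pd.read_csv(path)
    required = {"x_um", "y_um", "class"}
    missing = required - set(det.columns)
    if missing:
        raise ValueError(f"detections table lacks columns: {sorted(missing)}")
    return det
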