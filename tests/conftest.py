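import numpy as np
import pytest

from madmcornea import generate_positions, preset_config


@pytest.fixture(scope="session")
def small_config():
    """A small but fully featured cornea used by image-level tests."""
    return preset_config("WT", cornea_radius=600.0, target_density=2000.0,
                         n_events=10, seed=1)


@pytest.fixture(scope="session")
def small_positions(small_config):
    return generate_positions(small_config)


@pytest.fixture(scope="session")
def template_positions():
    """One mid-size monolayer shared as the geometric template by the
    replicate-heavy recovery tests (events are re-randomized per replicate,
    like analyzing both corneas of one animal)."""
    cfg = preset_config("WT", cornea_radius=1200.0, target_density=2000.0, seed=99)
    return cfg, generate_positions(cfg)


def match_detections(gt, det, radius_um=10.0):
    """Greedy class-aware matching of ground-truth cells to detections.

    Returns the number of true positives; each detection is consumed at
    most once and must lie within ``radius_um`` with the correct class.
    """
    from scipy.spatial import cKDTree

    if len(det) == 0:
        return 0
    tree = cKDTree(det[["x_um", "y_um"]].to_numpy())
    tp = 0
    used: set[int] = set()
    for _, row in gt.iterrows():
        d, i = tree.query([row.x_um, row.y_um], k=min(3, len(det)))
        for dd, ii in zip(np.atleast_1d(d), np.atleast_1d(i)):
            if dd < radius_um and int(ii) not in used \
                    and det["class"].iloc[int(ii)] == row.color:
                tp += 1
                used.add(int(ii))
                break
    return tp
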