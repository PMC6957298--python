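"""Tests of the MADM monolayer generator: geometry, event rules, rendering."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from madmcornea import (
    ConfigurationError,
    GeometryError,
    SimulationConfig,
    generate_positions,
    preset_config,
    render_channels,
    render_junctions,
    simulate_madm,
)
from madmcornea.simulate import (
    GENOTYPE_HET,
    GENOTYPE_MUT,
    GENOTYPE_WT,
    _draw_clone_size,
    _ztp_lambda,
    mean_cell_spacing,
)

UNIT_AREA_RADIUS = 1000.0 / np.sqrt(np.pi)  # disc with exactly 1 mm^2


class TestPositions:
    def test_count_fixed_by_construction(self):
        cfg = SimulationConfig(cornea_radius=UNIT_AREA_RADIUS, target_density=2500.0,
                               seed=1)
        pts = generate_positions(cfg)
        assert abs(len(pts) - 2500) <= 125
        # realized density within 5% of target
        assert abs(len(pts) / 1.0 - 2500) / 2500 < 0.05

    def test_zero_expected_count_gives_empty_set(self):
        cfg = SimulationConfig(cornea_radius=10.0, target_density=1.0, seed=0)
        assert generate_positions(cfg).shape == (0, 2)

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(cornea_radius=400.0, target_density=2000.0, seed=7)
        a = generate_positions(cfg)
        b = generate_positions(cfg)
        np.testing.assert_array_equal(a, b)

    def test_points_inside_disc_with_blue_noise_spacing(self, small_config,
                                                        small_positions):
        pts = small_positions
        r = np.hypot(pts[:, 0], pts[:, 1])
        assert np.all(r <= small_config.cornea_radius + 1e-6)
        d, _ = cKDTree(pts).query(pts, k=2)
        assert d[:, 1].min() > 0.4 * mean_cell_spacing(small_config)

    @pytest.mark.parametrize("kwargs", [
        {"target_density": -5.0},
        {"cornea_radius": 0.0},
        {"seg_probs": (0.5, 0.5, 0.5)},
        {"pixel_scale": -1.0},
        {"mode": "XY-MADM"},
    ])
    def test_invalid_configuration_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)


class TestCloneSizeLaw:
    def test_mean_parameterization_is_exact(self):
        # zero-truncated Poisson with the requested mean
        for mean in (1.0, 1.7, 3.0, 6.0, 10.2):
            lam = _ztp_lambda(mean)
            if mean <= 1.0:
                assert lam == 0.0
            else:
                assert lam / (1.0 - np.exp(-lam)) == pytest.approx(mean, rel=1e-9)

    def test_sampled_sizes_have_requested_mean(self):
        rng = np.random.default_rng(0)
        sizes = np.array([_draw_clone_size(rng, 6.0) for _ in range(4000)])
        assert sizes.min() >= 1
        assert sizes.mean() == pytest.approx(6.0, abs=3 * sizes.std() / np.sqrt(len(sizes)))


class TestMadmEvents:
    def test_g2x_only_gives_matched_red_green_pairs(self, small_positions,
                                                    small_config):
        cfg = preset_config("WT", cornea_radius=600.0, target_density=2000.0,
                            n_events=10, seed=2, seg_probs=(1.0, 0.0, 0.0),
                            base_clone_size=1.0,
                            dispersal_sigma={g: 0.0 for g in
                                             (GENOTYPE_WT, GENOTYPE_MUT, GENOTYPE_HET)})
        mono = simulate_madm(cfg, small_positions)
        counts = mono.counts()
        assert counts == {"red": 10, "green": 10, "yellow": 0}
        # each sibling pair within 2 mean cell diameters
        diam = 2.0 * np.sqrt(1e6 / cfg.target_density / np.pi)
        for _, ev in mono.single_labeled.groupby("event_id"):
            red = ev[ev.color == "red"][["x_um", "y_um"]].to_numpy()
            green = ev[ev.color == "green"][["x_um", "y_um"]].to_numpy()
            assert np.hypot(*(red[0] - green[0])) <= 2 * diam

    def test_g2z_only_gives_yellow_and_colorless_only(self, small_positions):
        cfg = preset_config("WT", cornea_radius=600.0, target_density=2000.0,
                            n_events=10, seed=3, seg_probs=(0.0, 1.0, 0.0))
        mono = simulate_madm(cfg, small_positions)
        counts = mono.counts()
        assert counts["red"] == 0 and counts["green"] == 0
        assert counts["yellow"] == 10
        assert (mono.cells.color == "colorless").sum() >= len(small_positions) - 30

    def test_genotype_color_bookkeeping(self, small_positions):
        gr = simulate_madm(preset_config("KO", cornea_radius=600.0,
                                         target_density=2000.0, n_events=15, seed=4),
                           small_positions)
        lab = gr.single_labeled
        assert (lab.loc[lab.color == "green", "genotype"] == GENOTYPE_MUT).all()
        assert (lab.loc[lab.color == "red", "genotype"] == GENOTYPE_WT).all()
        wt = simulate_madm(preset_config("WT", cornea_radius=600.0,
                                         target_density=2000.0, n_events=15, seed=4),
                           small_positions)
        assert (wt.single_labeled.genotype == GENOTYPE_WT).all()

    def test_every_single_labeled_cell_has_an_event(self, small_positions):
        mono = simulate_madm(preset_config("CK", cornea_radius=600.0,
                                           target_density=2000.0, n_events=12, seed=5),
                             small_positions)
        assert (mono.single_labeled.event_id >= 0).all()
        assert (mono.labeled.groupby("clone_id").size() >= 1).all()

    def test_zero_dispersal_clones_stay_near_founder(self, small_positions):
        cfg = preset_config("KO", cornea_radius=600.0, target_density=2000.0,
                            n_events=8, seed=6,
                            dispersal_sigma={g: 0.0 for g in
                                             (GENOTYPE_WT, GENOTYPE_MUT, GENOTYPE_HET)})
        mono = simulate_madm(cfg, small_positions)
        diam = 2.0 * np.sqrt(1e6 / cfg.target_density / np.pi)
        for _, clone in mono.single_labeled.groupby("clone_id"):
            pts = clone[["x_um", "y_um"]].to_numpy()
            founder = pts[0]
            assert np.max(np.hypot(*(pts - founder).T)) <= 2 * diam

    def test_labeled_cells_keep_body_separation(self, small_positions):
        mono = simulate_madm(preset_config("KO", cornea_radius=600.0,
                                           target_density=2000.0, n_events=12, seed=9),
                             small_positions)
        pts = mono.labeled[["x_um", "y_um"]].to_numpy()
        d, _ = cKDTree(pts).query(pts, k=2)
        assert d[:, 1].min() > 10.0  # well above detection resolution

    def test_expansion_fold_ratio_recovered(self, small_positions):
        # aggregate green/red converges to the fold ratio (here 6:1)
        greens = reds = 0
        per_event = []
        for seed in range(6):
            cfg = preset_config("KO", cornea_radius=600.0, target_density=2000.0,
                                n_events=35, seed=100 + seed, seg_probs=(1, 0, 0))
            mono = simulate_madm(cfg, small_positions)
            c = mono.counts()
            greens += c["green"]
            reds += c["red"]
            for _, ev in mono.single_labeled.groupby("event_id"):
                per_event.append(((ev.color == "green").sum(), (ev.color == "red").sum()))
        g = np.array([e[0] for e in per_event], dtype=float)
        r = np.array([e[1] for e in per_event], dtype=float)
        ratio = greens / reds
        n = len(per_event)
        se = ratio * np.sqrt(g.var(ddof=1) / (n * g.mean() ** 2)
                             + r.var(ddof=1) / (n * r.mean() ** 2))
        assert abs(ratio - 6.0) <= 3 * se

    def test_simulation_deterministic(self, small_positions):
        cfg = preset_config("CK", cornea_radius=600.0, target_density=2000.0,
                            n_events=10, seed=11)
        a = simulate_madm(cfg, small_positions).cells
        b = simulate_madm(cfg, small_positions).cells
        pd.testing.assert_frame_equal(a, b)

    def test_empty_positions_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_madm(SimulationConfig(seed=0), np.empty((0, 2)))


class TestRendering:
    def test_spot_maximum_at_transformed_pixel(self):
        cfg = SimulationConfig(cornea_radius=150.0, target_density=2000.0,
                               pixel_scale=3.0, photon_noise=False,
                               background_level=0.0, seed=0)
        cells = pd.DataFrame({"id": [0], "x_um": [100.0], "y_um": [100.0],
                              "color": ["red"], "clone_id": [0], "event_id": [0],
                              "genotype": ["WT"]})
        from madmcornea.simulate import SimulatedMonolayer
        img, scale = render_channels(SimulatedMonolayer(cells, cfg))
        half = 150.0 + 30.0
        row, col = np.unravel_index(np.argmax(img[0]), img[0].shape)
        assert (row, col) == (round((100 + half) / 3.0), round((100 + half) / 3.0))
        assert img[1].max() == 0

    def test_yellow_cell_peaks_in_both_channels_at_same_pixel(self):
        cfg = SimulationConfig(cornea_radius=150.0, target_density=2000.0,
                               photon_noise=False, background_level=0.0, seed=0)
        cells = pd.DataFrame({"id": [0], "x_um": [-40.0], "y_um": [25.0],
                              "color": ["yellow"], "clone_id": [0], "event_id": [0],
                              "genotype": ["HET"]})
        from madmcornea.simulate import SimulatedMonolayer
        img, _ = render_channels(SimulatedMonolayer(cells, cfg))
        assert np.argmax(img[0]) == np.argmax(img[1])

    def test_render_deterministic(self, small_positions, small_config):
        mono = simulate_madm(small_config, small_positions)
        a, _ = render_channels(mono)
        b, _ = render_channels(mono)
        np.testing.assert_array_equal(a, b)
        ja, _ = render_junctions(small_positions, small_config)
        jb, _ = render_junctions(small_positions, small_config)
        np.testing.assert_array_equal(ja, jb)

    def test_field_too_small_raises(self, small_positions, small_config):
        mono = simulate_madm(small_config, small_positions)
        with pytest.raises(GeometryError):
            render_channels(mono, field_um=100.0)

    def test_junctions_need_three_points(self, small_config):
        with pytest.raises(GeometryError):
            render_junctions(np.array([[0.0, 0.0], [10.0, 10.0]]), small_config)

    def test_three_points_partition_into_three_regions(self):
        from scipy import ndimage

        cfg = SimulationConfig(cornea_radius=150.0, target_density=2000.0,
                               photon_noise=False, pixel_scale=1.0, seed=0)
        pts = np.array([[0.0, 0.0], [60.0, 10.0], [-40.0, 55.0]])
        img, _ = render_junctions(pts, cfg)
        mask = img < img.min() + 0.3 * (img.max() - img.min())
        _, n = ndimage.label(mask)
        assert n == 3

    def test_hexagonal_lattice_renders_expected_enclosed_faces(self):
        from scipy import ndimage
        from scipy.spatial import Voronoi

        # hexagonal lattice inside the disc
        cfg = SimulationConfig(cornea_radius=200.0, target_density=2000.0,
                               photon_noise=False, pixel_scale=1.0, seed=0)
        a = 22.0
        xs = np.arange(-9, 10) * a
        ys = np.arange(-9, 10) * a * np.sqrt(3) / 2
        pts = np.array([[x + (j % 2) * a / 2, y]
                        for j, y in enumerate(ys) for x in xs])
        pts = pts[np.hypot(pts[:, 0], pts[:, 1]) < 190.0]
        img, scale = render_junctions(pts, cfg)

        # oracle: within a central window (no rim ambiguity), the number of
        # fully enclosed faces equals the number of positions whose bounded
        # Voronoi region lies entirely in the window
        half = cfg.cornea_radius + 30.0
        vor = Voronoi(pts)
        # choose a window edge well away from every tessellation vertex so
        # no face is ambiguously cut by the crop
        inner = vor.vertices[np.max(np.abs(vor.vertices), axis=1) < 160]
        for w in np.arange(100.0, 140.0, 0.5):
            if np.min(np.abs(np.abs(inner) - w)) > 4.0:
                break
        expected = 0
        for ridx in vor.point_region:
            reg = vor.regions[ridx]
            if reg and -1 not in reg and np.all(np.abs(vor.vertices[reg]) < w):
                expected += 1

        lo = int((-w + half) / scale)
        hi = int((w + half) / scale) + 1
        crop = img[lo:hi, lo:hi]
        mask = crop < img.min() + 0.3 * (img.max() - img.min())
        lab, n = ndimage.label(mask)
        border = set(np.unique(np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]])))
        enclosed = n - len(border - {0})
        assert enclosed == expected


class TestPresets:
    def test_presets_encode_study_conditions(self):
        wt, ck, ko = (preset_config(n) for n in ("WT", "CK", "KO"))
        assert wt.mode == "WT-MADM" and ck.mode == ko.mode == "GR-MADM"
        assert wt.expansion_fold[GENOTYPE_MUT] == 1.0
        assert ck.expansion_fold[GENOTYPE_MUT] == 3.0
        assert ko.expansion_fold[GENOTYPE_MUT] == 6.0
        # dispersal ordering: scattered CK, intermediate WT, packed KO
        assert ck.dispersal_sigma[GENOTYPE_MUT] > wt.dispersal_sigma[GENOTYPE_MUT] \
            > ko.dispersal_sigma[GENOTYPE_MUT]

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigurationError):
            preset_config("CKO")
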