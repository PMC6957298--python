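# madmcornea

Quantification of mosaic (MADM) corneal endothelium: junction-based cell
segmentation and morphometry, red/green/yellow labeled-cell detection,
twin-spot discovery, density-based cluster-dispersion analysis, and
green/red ratio reporting — together with a generative simulator of
MADM-labeled monolayers so that every stage is testable against exact
ground truth, without any animal data.

## Who this is for and what it computes

In a MADM (mosaic analysis with double markers) cornea, rare Cre-mediated
interchromosomal recombination marks single cells: G2-X segregation
produces a red (RFP⁺) / green (GFP⁺) sibling pair — in a mutant mosaic the
green daughter is homozygous mutant and the red one homozygous wild type —
while G2-Z and G0/G1 events produce yellow (double-labeled) cells.  Each
single-labeled founder expands into a clone.  Three readouts quantify the
biology:

* **Green/red cell ratio** `R = N_green / N_red` over the single-labeled
  cells of a cornea — an unbiased proxy for mutant-versus-wild-type clonal
  expansion, because every G2-X event contributes exactly one clone of
  each color.
* **Twin spots** — isolated groups of adjacent red and green cells
  (single-linkage components at radius 248 µm = 82 px, at least 200 µm
  from any other single-labeled cell), whose per-spot sizes and ratios
  resolve expansion at single-event resolution.
* **Percent-in-cluster** — the fraction of single-labeled cells of one
  color assigned to a density cluster (ε = 136 µm = 45 px, minimum
  density 4, counted inclusively), which separates scattering mutants from
  tightly clustering ones.

Monolayer health is quantified from junction-label (ZO-1-like) images by a
smoothing → h-minima seeding → seeded-watershed (Dirichlet) partition,
yielding density (cells/mm², border cells weighted ½), cell area,
circularity 4πA/P², and neighbor counts, sampled at four central and four
peripheral sites.

All of this runs on standard two-channel and single-channel TIFFs with a
physical pixel scale (default 248/82 ≈ 3.0244 µm/px).  The simulator
generates blue-noise near-hexagonal monolayers (1500–4000 cells/mm²) on a
cornea disc, plants recombination events with genotype-specific clone
expansion (WT ≈ 1×, CK-like ≈ 3×, KO-like ≈ 6×) and dispersal (scattered
vs contact-packed), and renders panoramas and boundary images with
optional noise and epithelial-streak artifacts.  See `docs/methods.md`
for the model and its assumptions.

## Worked example

```python
from madmcornea import (preset_config, generate_positions, simulate_madm,
                        render_channels, detect_labeled_cells,
                        green_red_ratio, find_twin_spots, twin_spot_stats)

cfg = preset_config("KO", cornea_radius=600.0, target_density=2000.0,
                    n_events=10, seed=3)       # null-allele mosaic, 6x expansion
pos = generate_positions(cfg)                  # 2262 cells on the 0.6-mm disc
mono = simulate_madm(cfg, pos)                 # ground truth cell table
img, scale = render_channels(mono)             # (2, 418, 418) uint16 panorama

half = cfg.cornea_radius + 30.0
cells = detect_labeled_cells(img, scale, origin_um=(-half, -half))
print(cells.counts())
ratio, counts = green_red_ratio(cells)
print(round(ratio, 2))
stats = twin_spot_stats(find_twin_spots(cells.detections))
print(stats["n_spots"], stats["pooled_green_red_ratio"])
```

prints

```
{'red': 4, 'green': 27, 'yellow': 7}
6.75
2 6.75
```

— this cornea carried 10 recombination events of which three were G2-X;
the wild-type red clones stayed at one or two cells while the mutant
green clones expanded ~6-fold, every labeled cell was detected and
classified correctly, and the single-labeled cells grouped into two twin
spots (one of them a merger of two adjacent events — on this small test
disc events sit closer than on a full cornea).  The per-cornea ratio 6.75
scatters around the planted 6× fold because event counts are small —
which is exactly why ratios are pooled over corneas:
the acceptance run below pools ≥200 events per genotype and recovers
1.07 / 3.08 / 5.79 for the planted 1× / 3× / 6× folds.

The same stages are scriptable from the shell (`madm-cornea simulate /
segment / detect / twinspots / cluster / report / pipeline`), and the
numbered drivers under `analysis/` run the full simulated-cohort study:
`01_simulate_cohort.py` → `06_cornea_reports.py` write per-cornea tables
and the per-genotype summary under `results/` (with the default desk-scale
cohort: pooled green/red ratio 1.04 ± 0.13 for WT-MADM, 3.88 ± 0.53 for
CK-like and 7.00 ± 0.30 for KO-like mosaics over four corneas each, and
mean green percent-in-cluster 12.5 / 5.6 / 100 for WT / CK / KO).

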