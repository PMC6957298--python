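# Methods

## The quantification problem

A MADM (mosaic analysis with double markers) cornea contains rare,
randomly timed recombination events that mark single cells and their
progeny: G2-X segregation yields a red/green sibling pair (in GR-MADM the
green daughter is homozygous mutant and the red one homozygous wild type;
in WT-MADM both are wild type), G2-Z yields a yellow/colorless pair, and
G0/G1 recombination yields a single yellow cell.  Quantifying such corneas
means (i) segmenting the monolayer from junction-label images and
measuring density and shape, (ii) detecting and color-classifying labeled
cells in two-channel panoramas, (iii) grouping isolated red+green
neighborhoods into twin spots, (iv) measuring how tightly same-color cells
cluster, and (v) reporting green/red count ratios as the proxy for mutant
clonal expansion.  Because no imaging data are deposited alongside the
study design this package implements, every stage is validated against a
generative simulator whose ground truth is known exactly.

## Simulator

**Geometry.**  The cornea is a disc (default radius 1500 µm, from the
statement that eight ~0.031-mm² sampling sites cover ≈0.25 mm² = 3.6% of
the endothelium, i.e. ≈6.9 mm² total).  Cell centers are drawn by Bridson
Poisson-disc sampling (blue noise, minimum spacing `sqrt(0.55/density)`),
thinned to exactly `round(density·area)` points and relaxed with two Lloyd
iterations, giving a near-hexagonal epithelium-like packing (mean neighbor
count ≈ 6) at the configured density (default 2500 cells/mm², within the
healthy range of 1500–4000).  The realized count is exact by construction;
minimum spacing stays above 0.4× the mean hexagonal spacing.

**Events.**  `n_events` anchor cells are chosen uniformly (optionally
with a minimum pairwise spacing for planted-recovery experiments); each
event draws a segregation mode from `seg_probs` (default 0.2/0.2/0.6 for
G2-X/G2-Z/G0-G1, which makes yellow the most common label, as observed in
WT-MADM corneas).  G2-X founders occupy adjacent lattice positions.

**Clone sizes.**  A single-labeled founder expands into a clone whose
size is drawn from a zero-truncated Poisson parameterized so that
E[size] = `base_clone_size × expansion_fold[genotype]` exactly.  The exact
mean parameterization is what makes the pooled green/red count ratio an
unbiased estimator of the fold ratio (the obvious alternative,
`max(1, Poisson(fold))`, has mean `fold + e^(−fold)` and would bias the
ratio for small folds).  `base_clone_size = 1.7` is calibrated
analytically so that the WT twin-spot size distribution (sum of two such
clones) puts ≈80% of spots at 2–4 cells, matching the reported ≈83%
small-spot fraction in wild-type tissue.

**Dispersal.**  Clone progeny take cumulative isotropic Gaussian steps of
scale `dispersal_sigma[genotype]` per division, reflected at the cornea
rim.  Cells are bodies, not points: every placement keeps at least
0.75× the mean cell spacing from every previously placed labeled cell.
When sigma falls below that contact distance the clone cannot out-run its
own footprint and grows instead as a compact contact-packed clump around
the founder — which is exactly the "packed together, often in direct
contact" phenotype of null-allele clones.  Preset scales: WT 20 µm
(progeny stay within one or a few cell diameters), CK-like 400 µm
(progeny quasi-uniformly scattered across the monolayer), KO-like 8 µm
(contact-packed clumps).  The WT/CK/KO presets carry expansion folds
1×/3×/6× on the mutant (green) clone, per the reported three- and
six-fold green/red ratio increases.

**Rendering.**  Labeled cells become Gaussian spots (σ = 4 µm, amplitude
3000 over a background of 100 counts) in a two-channel uint16 panorama at
the panorama pixel scale 248/82 = 3.0244 µm/px; yellow cells appear in
both channels at the same position.  Optional Poisson photon noise and
green "radial streak" artifacts (emulating epithelial bleed-through in
folded flat-mounts) can be added.  Junction-label images draw the
Dirichlet tessellation ridges of the cell positions (including clipped
unbounded ridges) with a 1.5-µm Gaussian profile; boundary imaging is
done at high magnification, so those images default to the same pixel
scale but all validation uses 1 µm/px.  All randomness flows from one
seed through fixed-order substreams, so a config reproduces bit-identical
tables and images.

**What the simulator does not model.**  3D tissue and z-stacks (inputs
are assumed max-projected), stromal/epithelial layers beyond the streak
artifact, cell-cycle mechanics (only final clone-size distributions; the
data cannot distinguish extra division rounds from faster cycling),
intensity variation between cells, chromatic registration error, or
stitching seams.  Passing tests therefore demonstrate the correctness of
the measurement pipeline on idealized but geometrically realistic
monolayers, not robustness to every artifact of real confocal panoramas.

## Segmentation and morphometry

Junction images are smoothed (Gaussian, σ = 1.5 µm), seeds are extracted
as h-minima of the smoothed junction signal (depth 10% of the dynamic
range), and a seeded watershed partitions the field with boundaries
constrained to the bright ridges — a seeded Dirichlet partition in the
limit of thin ridges.  Cells touching the image frame are flagged
`is_border`, excluded from shape statistics, and weighted ½ in density
(standard edge correction).  Area is pixel count × scale²; perimeter uses
the Crofton estimator (4 directions), which keeps the circularity
4πA/P² of a discretized disc within 2% of 1.  Neighbors share ≥1 px of
boundary.  On noise-free renders of ≥400 cells, interior cell counts are
recovered within 2% and the median per-cell area error against the
generating tessellation is <5% at 1 µm/px; planted density is recovered
within 5% under Poisson noise.  Regional sampling places one central and
one peripheral 177-µm site per quadrant (central: r ≤ 1250 µm;
peripheral: within 200 µm of the rim), and per-class summaries average
the four sites.

## Labeled-cell detection

Each channel is band-pass filtered with a difference of Gaussians
(σ = 4 µm against a 6× wider background; the wide surround keeps
contact-packed clump interiors as local maxima).  Maxima above a robust
MAD-based threshold, with an 8-µm duplicate-suppression radius, become
candidates; candidates from both channels within a 5-µm pairing radius
merge into one detection carrying both intensities.  A detection is
positive in a channel when its background-subtracted intensity exceeds
max(6×MAD noise, 5% of the brightest spot); both channels positive →
yellow, one → that color.  These floors scale with the image, so
classification is invariant under rescaling both channels.  Long
(>100 µm), thin (aspect >5) bright components in the green channel are
removed before peak picking, as a reproducible stand-in for the manual
curation of epithelial bleed-through streaks; removals are counted in the
output metadata.  On simulated panoramas at default noise, recall and
precision are ≥0.98 (and exact in noise-free renders).

## Twin spots

Single-labeled (red/green) detections are linked whenever closer than the
grouping radius (82 px = 248 µm); connected components containing both
colors are twin-spot candidates.  The isolation rule (no outside
single-labeled cell within 200 µm of any member) is automatic when the
isolation distance does not exceed the grouping radius, and enforced
explicitly otherwise.  Components spanning more than twice the grouping
radius are flagged as possible mergers of overlapping clones — a
deterministic, auditable replacement for manual elimination — and kept
separable in summaries.  Membership agrees exactly with a brute-force
all-pairs construction, and planted isolated events are recovered with
100% recall and precision.

## Cluster dispersion

The clustering is the classic density-based construction on point
centroids in physical µm (hence invariant to detected blob size and
shape): a core point has ≥ `min_density` points within ε *including
itself* (ε = 45 px = 136 µm, min 4) — this inclusive reading makes
"minimum density" equal the minimum cluster size, which is how the
parameter is named in the toolbox this mirrors; clusters are connected
components of core points under ε-reachability; border points join the
cluster of their *nearest* core point (ties to the lowest index), which
removes classic DBSCAN's input-order dependence.  Colors are clustered
separately by default.  `percent_in_clusters` = 100 × clustered/total per
color.  The implementation is checked for exact membership agreement
against a by-definition O(n²) oracle on 500 random instances, and core
points additionally against scikit-learn's DBSCAN.

## Reporting and replicates

Each cornea yields one validated report (counts, green/red ratio with an
explicit undefined flag when red = 0, densities, morphometry, twin-spot
and cluster summaries, parameter echo, version, seed).  Batch mode emits
a tidy long table (cornea × metric) plus means ± SEM per genotype mode;
both corneas of a simulated animal are treated as independent replicates
because event number and timing are uncorrelated between eyes.
Inferential statistics (ANOVA, post-hoc tests) are deliberately out of
scope; the long table is the input those tests would consume.

For the genotype dispersion ordering (KO > WT > CK in green
percent-in-cluster), a replicate pools 15 simulated corneas per genotype
before computing the percentage.  A wild-type cornea carries only ~4 G2-X
events, so its per-cornea percentage is zero-inflated and a strict
three-way per-cornea ordering would be statistically meaningless; pooling
mirrors reporting the statistic per genotype group.  The two-way KO > CK
comparison is well separated per cornea and is tested per cornea over 100
replicates.

## Problem sizes and numerical choices

Validation runs use 600–1200-µm discs at 1500–2500 cells/mm² (full-size
1500-µm corneas behave identically; the replicate-heavy suites share one
monolayer template across replicates and re-randomize events, like eyes
of one animal).  Degenerate inputs are defined: empty position sets and
empty detection tables propagate as empty outputs; constant images warn
and return empty tessellations; zero-area polygons are dropped with a log
entry; a zero red count flags the ratio undefined rather than raising.
Coordinates are µm everywhere inside the library; pixel conversions
happen only at image I/O with x right / y down, 0-based indices, and
pixel centers at integer multiples of the scale.

## Known limitations

* The filter chain of the original boundary-detection macro is
  unpublished; the chain here (smooth → h-minima seeds → seeded
  watershed) reproduces its described structure but not necessarily its
  exact parameters.
* The elongation filter is a proxy for manual curation of epithelial
  bleed-through; on real panoramas curly or short streaks would survive
  it.
* The grouping radius (248 µm) is treated as a free parameter defaulted
  to the published value; the original "best fit" criterion that selected
  it is not reproducible from the text.
* Clone dispersal is a phenomenological random walk; it reproduces the
  scattered/packed phenotypes but is not a mechanistic migration model.
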