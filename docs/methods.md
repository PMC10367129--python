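# Methods

`lipogate` reimplements, as an open and testable pipeline, the image-based
phenotyping workflow used to characterise gene-expressing giant liposomes
("synthetic cells") on an imaging flow cytometer: per-event feature
extraction over a custom object mask, followed by sequential gating
cascades that identify intact liposomes, quantify their morphology, and
score gene-encoded functional modules (lumen expression, DNA replication
condensates, cytoskeletal filaments, membrane relocalization, and
membrane-lipid synthesis). Because no instrument data ship with the
package, a synthetic event generator with known ground truth is a
first-class component: every cascade is certified by parameter-recovery
experiments on populations it renders.

## Synthetic event model

An event is a 90 x 90 px two-channel tile (membrane dye, reporter) at
0.33 um/px, emulating a 60x magnification acquisition. Objects are drawn
as line-of-sight integrals through simple 3D bodies:

- **Membrane** — a thin spherical shell of thickness 0.3 um. The projected
  path length through the shell produces the characteristic
  limb-brightened ring (bright rim, faint lumen chord at ~20 % of rim
  brightness), not a flat annulus. Rods are capsules (segment + hemicaps)
  treated the same way; doublets are two adhered spheres of unequal
  diameter plus the edge-on bright chord of their flat adhesion disc;
  multilamellar/multivesicular vesicles add 1–4 nested inner shells, the
  first of which is prominent (>= 0.38 of the outer radius) and none of
  which is below the ~2 um resolvable diameter — mirroring how that
  phenotype is defined by *visible* internal structure in the first place.
- **Aggregates** — unions of 3–8 overlapping bright solid blobs with
  multiplicative speckle; **debris** — a single dim solid blob under
  8 um^2 true area.
- **Reporter patterns** — `none`; `lumen` (chord through the enclosed
  ball); `blob` (a Gaussian condensate carrying the same integrated signal
  as the homogeneous pattern, sigma = lumen diameter / 20, floored at
  0.2 um); `filaments` (1–4 random chords of sigma 0.2 um carrying 4x the
  per-pixel brightness over a 0.25x free-monomer background); `membrane`
  (the shell pattern, e.g. a relocalized or lipid-binding reporter).

The pattern is convolved with a Gaussian PSF of width
sqrt(psf_sigma_infocus^2 + defocus_sigma^2) (in-focus sigma 0.4 um),
box-binned 3x to the detector grid, offset by a constant background (5 %
of the default membrane brightness), then corrupted by Poisson shot noise
and Gaussian read noise (sigma 3) and quantised to integer counts so that
stored 16-bit tiles round-trip exactly. Per-event brightness is lognormal
(median 300, sigma 0.15 in log space) — the within-sample dye variability
of one preparation; reporter brightness is lognormal with sigma 0.4–0.5,
spanning roughly an order of magnitude as gene-expression levels do.
In-focus events carry |N(0, 0.12)| um of residual defocus; the
out-of-focus class draws U(1.5, 3) um.

Defaults were chosen once for plausibility at the stated magnification
and are config-exposed (`OpticsModel`, `PhenotypeSpec`); no absolute
radiometric calibration to any instrument is attempted or implied. Two
defaults deserve explicit justification:

- **Rod elongation U(1.6, 2.4).** Rod-shaped liposomes are classified
  *downstream* of an identification gate that keeps only aspect ratio
  > 0.4. A capsule of elongation ~2.6 or more falls below that cut, so
  rods that survive real identification are necessarily moderate in
  elongation; the generator draws them accordingly. Strongly elongated
  capsules (elongation 3–4) remain renderable and are used in the feature
  tests (their aspect ratio is asserted to fall below 0.4).
- **Class separability.** The generator's contract includes that every
  phenotype class is recoverable by the cascades with >= 0.9
  recall/precision at default SNR. Where an early draft of a phenotype
  was visually ambiguous (e.g. multilamellar vesicles whose single inner
  vesicle was below the resolution limit), the phenotype definition was
  sharpened to match what the corresponding visual class actually means,
  rather than relaxing the recovery contract.

What the generator does **not** emulate: diffraction sidelobes and the
TDI sensor, flow-induced deformation, speed-bead artifacts, neighbouring
objects in one tile, chromatic offsets between channels, and instrument-
specific feature scales. Passing recovery tests therefore certify the
pipeline's logic and the features' discriminative power under this image
model — not performance on any particular instrument's raw files.

## Masks

Segmentation is Otsu thresholding on the membrane channel with the
threshold clamped to [median + 4 sigma, median + 12 sigma], where sigma is
a robust tile noise scale (MAD, floored at 2 % of the dynamic range).
The clamp fixes Otsu's two classical failure modes on event tiles: on a
mostly-background tile with a dim object it splits the background noise;
on a tile dominated by a bright internal structure it crops the dimmer
membrane away. The thresholded image is reduced to its largest connected
component, morphologically closed (radius 2 px), hole-filled (so the dark
lumen inside the ring belongs to the mask) and dilated by a configurable
radius (default 2 px) so the mask encompasses both lumen and membrane.
Events with no segmentable object are flagged (`mask_ok = 0`) and fail all
gates; they are counted, never silently dropped.

## Feature definitions

All features are computed inside the mask. Scale-dependent features do
not numerically match any proprietary implementation; their cut-offs are
therefore calibrated (below) rather than copied.

- `area` = pixel count x pixel_size^2 (um^2); `diameter` =
  2 sqrt(area/pi).
- `aspect_ratio` = minor/major axis of the mask's second-moment ellipse.
- `circularity` = mean boundary-to-centroid distance / its standard
  deviation, capped at 100. (The mean/sd form is used rather than
  mean/variance because only the ratio of same-unit quantities is
  scale-invariant.)
- `intensity`, `max_pixel` — background-subtracted sum and maximum;
  background is the median outside the 3-px-dilated mask.
- `std_dev` — SD of raw mask pixels.
- `gradient_rms` — RMS Sobel gradient magnitude over the mask / mean mask
  intensity x 100 (focus metric); `contrast` — RMS 3x3 Laplacian
  magnitude, normalised the same way (sharp-structure metric).
- `compactness` = r_eq / r_gyr, the equivalent-circle radius over the
  background-subtracted intensity-weighted radius of gyration; higher
  means more condensed signal.
- **Haralick textures** `h_{homogeneity,correlation,entropy,contrast}_
  {mean,std}` — the image is min–max quantised to 32 gray levels inside
  the mask; symmetric normalised co-occurrence matrices are accumulated
  for the four offsets (→, ↓, ↘, ↙) at a granularity of 2 px, counting
  only pixel pairs that both lie in the mask; homogeneity
  Σ p/(1+|i−j|), correlation Σ p (i−μ)(j−μ)/σ² (0 by convention when
  σ = 0), entropy −Σ p ln p, contrast Σ p (i−j)²; mean and SD are taken
  across the four offsets. The granularity default of 2 px was chosen as
  the scale at which mesoscale membrane texture (neck of a doublet vs the
  straight flanks of a rod) is most discriminative; it is config-exposed.
- **Bright detail similarity R3** — each channel minus its morphological
  opening with a 3-px-radius disc, floored at 0; the Pearson correlation
  rho of the two residues over the mask is reported as
  −log10(1 − min(rho, 1 − 1e−6)), floored at 0 (cap 6).
- `molecules_in_sphere(c, d)` = c · (π/6) d³ · N_A with litre/um³
  conversion — the detection-limit bookkeeping (500 nM in a 4 um vesicle
  ≈ 1.0 x 10^4 molecules).

## Gating and calibration

Gates are declarative: 1D thresholds/intervals, rectangles, and polygon
regions in a feature-pair plane (even–odd membership, so disjoint lobes
and holes work; an empty polygon list is a region matching nothing).
Pipelines apply gates sequentially with per-stage accounting
(entering/passing/undefined; undefined features fail, mirroring how
unanalysable objects are excluded in practice).

Scale-free cut-offs are hard-coded: area > 8 um^2, aspect ratio > 0.4.
Every scale-dependent cut-off is calibrated on seed-fixed labelled
synthetic populations (350 events/class) and shipped as a YAML preset
(`lipogate/presets/default_gates.yaml`, regenerated by
`scripts/calibrate_presets.py`):

- 1D thresholds maximise balanced accuracy between the target class and
  the rest; screening stages that must not consume good liposomes use a
  positive-recall floor (0.995) when picking the cut.
- 2D hand-drawn-style regions are the posterior >= level contour of a
  quadratic discriminant fitted to the two named features, traced to
  closed polygons by marching squares on a zero-padded grid. Rejection
  regions (debris, dense aggregates, texture aggregates, lamellarity
  exclusion) raise the level above 0.5 until at most 0.1–0.5 % of the
  to-be-kept class falls inside — the polygon analogue of the recall
  floor.
- A linear size calibration (mask-equivalent diameter → true diameter,
  fitted on reference spheres) removes the dilation + PSF margin from
  reported size statistics, in the same spirit as bead-based size
  calibration on real instruments.

`threshold_from_negative` implements negative-control thresholding as an
order statistic: the smallest observed negative value with at most
floor(max_fpr · n) negatives above it, which meets the FPR bound for
every sample size (a plain linear quantile does not for small n).

## Cascades

- **identify** — (1) area > 8 um^2; (2) aspect ratio > 0.4; (3) reject
  the debris region and (4) the dense-aggregate region of the
  (area, log10 intensity) plane; (5) keep gradient RMS above the focus
  cut; (6) keep H-homogeneity above its cut; (7) reject the aggregate
  region of the (H-correlation mean, H-correlation std) plane. The
  failing stage fixes the event's label (debris / aggregate /
  out_of_focus / rejected); survivors are good liposomes.
- **morphology** — circularity cut splits spherical from nonspherical;
  spherical events are unilamellar vs multilamellar in
  (compactness, max pixel); nonspherical events are rod vs doublet in
  (H-entropy std, H-correlation std); events matching no region keep an
  explicit `unclassified` / `nonspherical_other` label.
- **expression** — reporter intensity threshold; also reports size
  distributions of expressing vs nonexpressing and the intensity–area
  correlation.
- **replication** — intensity cut for negatives, then blob vs homogeneous
  in (std dev, H-homogeneity mean).
- **filaments** — intensity cut, then filament vs no-filament in
  (std dev, contrast).
- **relocalization** — a lamellarity exclusion gate in (H-correlation
  std, H-contrast std) on the membrane channel, then bright-detail
  similarity (membrane, reporter) above its cut → membrane-localized
  (active).
- **ps** — positivity threshold from a negative-control sample at
  max FPR 5 %; the achieved control FPR is reported.

## Recovery experiments (what the tests certify)

`lipogate.recovery` renders seed-fixed mixtures and scores per-class
recall/precision and the deviation of recovered class fractions from the
generator weights in binomial SE units. The identification+morphometry
run uses 5,000 events over seven classes (sphere 0.20, multilamellar
0.14, rod 0.08, doublet 0.18, aggregate 0.12, debris 0.16, defocused
0.12 — junk over-represented relative to a clean preparation so every
rejection branch is exercised); the reporter modules use 2,000-event
mixtures (expression 60/40; replication 40/35/25; filaments 20/55/25;
relocalization 50/50; PS 60/40 plus 1,000-event negative controls). The
module mixture weights are testing conditions chosen for stable per-class
metrics; observed fractions in any real sample are properties of that
sample, not of the pipeline. These problem sizes keep a full suite run in
the minutes range while leaving per-class counts of 160+ events.

## Numerical notes and limitations

- Determinism: every random draw flows from one `numpy` Generator per
  operation seed; identical seeds give bit-identical tiles, tables and
  labels.
- GLCM offsets with no valid pixel pair are dropped from the mean/SD; a
  mask with fewer than two pixels (or none) yields NaN features and a
  flagged row.
- Constant textures: correlation 0 (sigma = 0), entropy 0, homogeneity 1.
- Circularity is capped at 100 when the boundary-distance SD collapses.
- The BDS score caps at 6 (epsilon 1e−6) for perfectly correlated
  residues and floors at 0 for anticorrelated ones.
- The paper-scale percentages a real sample produces (fractions of good
  liposomes, expressing vesicles, etc.) depend on the preparation and are
  not reproduction targets; the pipeline's claims are the recovery
  metrics above plus the closed-form worked examples.
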