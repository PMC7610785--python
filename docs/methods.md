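# Methods

`ramanev` quantifies the cellular uptake of deuterium-labelled extracellular
vesicles (EVs) from confocal Raman hyperspectral images, and the deuteration
of single optically trapped EVs from their spectra. This note describes the
underlying models, the synthetic data used to validate every stage, the
numerical choices, and the limits of what the tests demonstrate.

## The measurement problem

Cells grown on deuterated nutrients incorporate C–D bonds into the EVs they
secrete. C–D stretching vibrations appear around 2140 cm⁻¹, inside the Raman
"silent region" (1800–2800 cm⁻¹) where endogenous biomolecules have no
bands, so deuterium acts as a bio-orthogonal tag: any signal in the
2025–2275 cm⁻¹ window of a cell image marks EV-derived material. A
hyperspectral image is a cube of H×W (optionally ×Z) pixels, each carrying a
full spectrum on a shared wavenumber grid (0–3700 cm⁻¹ at ~11 cm⁻¹
resolution; 0.5 µm pixels in the emulated configuration). EVs (~120 nm) are
well below the optical resolution, so detected deuterium signal corresponds
to sub-pixel EV clusters.

## Preprocessing

Per pixel, in order:

1. **Crop** to [400, 3600] cm⁻¹ (removes the laser line; both ends
   configurable).
2. **'Shape' baseline filter.** Autofluorescence is a smooth additive
   background varying over hundreds of cm⁻¹. The baseline is estimated as a
   grey-scale opening (flat structuring window, width `shape_size` =
   500 cm⁻¹ ≈ 45 bins) followed by a moving-average smoothing with the same
   window; `corrected = spectrum − baseline` reconstructs the input exactly.
   Opening follows convex stretches of a smooth background exactly and
   undercuts concave stretches by ≈ |b″|·(w/2)²/2, so with the default
   window the residual under realistic backgrounds is well below the Raman
   bands; peak areas (measured above a local linear background) are
   preserved to ≈1% for peaks narrower than `shape_size`/5.
3. **Area normalization** (optional, on by default for the spectral route):
   each spectrum scaled to unit trapezoidal area. All-zero/degenerate pixels
   are flagged in a quality mask rather than divided.
4. **Exterior background subtraction.** The mean spectrum of pixels exterior
   to the cell (substrate, buffer, optics) is subtracted from every pixel.
   The exterior is located automatically: Otsu threshold on the whole-cell
   band image, dilated by a safety margin, complemented.

**Two routes through the chain.** Per-pixel area normalization rescales each
pixel by its own total signal; cell interior and exterior scale differently,
which biases any comparison of intensities *across* pixels. The pipeline
therefore quantifies on a *linear* cube (steps 1, 2, 4 — no normalization)
and reserves the fully normalised cube for visualization, band images, the
FWHM metric and PCA spectra, where only spectral shape matters. Negative
intensities after subtraction are retained to keep the chain linear.

## Univariate band imaging

Band images integrate the preprocessed spectrum over fixed windows
(trapezoid on the exact window, edge bins interpolated): 775–805 cm⁻¹
(nuclei, DNA phosphodiester), 985–1015 (nucleoli, phenylalanine), 1425–1485
(lipids, CH₂ bend), 1635–1685 (proteins, amide I), 2025–2275 (deuterium,
C–D) and 2800–3000 (whole cell, C–H stretch). Composites are additive blends
of min-max-scaled maps (deuterium red, nucleoli cyan, nuclei blue, lipids
yellow, proteins green), so they are independent of map order.

Relative deuterium content is additionally scored by the **FWHM** of the
2025–2275 cm⁻¹ peak: the sharper the peak, the higher the relative
deuterium content. The window maximum is located per pixel and half-height
crossings interpolated linearly between bins; on Gaussian peaks the error is
under one bin width for σ between 10 and 40 cm⁻¹. Pixels whose window
maximum does not exceed a noise floor (mean + 3 SD of the exterior window
maxima) receive the sentinel FWHM = 250 cm⁻¹ (the window width); the score
map is width/FWHM, so 1 means "no deuterium".

## Deuterium detection and the net band integral

Detection thresholds the deuterium band image at `mean + k·SD` of the
exterior pixels (k = 3 by default; if the exterior SD is degenerate, e.g.
noise-free synthetic data, detection falls back to a high exterior quantile
with a scale-aware absolute floor). One subtlety motivates a deliberate
design choice: a plain band integral inherits each pixel's smooth
baseline-estimation residual coherently across all window bins, which makes
its noise right-skewed and spatially coherent — at the 3σ rule the measured
exterior false-positive rate was ~4× the Gaussian bound. The quantification
map is therefore the **net band integral**: the same trapezoid minus the
area of a chord anchored at the mean of the three bins at each window edge.
For a C–D peak (σ ≈ 25 cm⁻¹) centred in the 250 cm⁻¹ window the chord
removes <1% of the signal and stays exactly proportional to the planted
amplitude, while the noise becomes near-Gaussian. Plain integrals remain the
band-imaging route.

Because real deuterium signal is cluster-sized, the full pipeline by default
prunes isolated single-pixel positives (no positive 8-neighbour); the
detection function itself leaves pruning off unless asked.

## Uptake quantification

- **Segmentation**: Otsu threshold on the whole-cell band image → binary
  closing (radius 1 px) → largest connected component → hole filling. The
  membrane is the mask's 8-connected boundary. Multi-cell images can be
  split into components above a minimum area. The recipe is a conventional
  choice (exposed in the config), not a claim about the best segmenter.
- **Membrane distances**: for every deuterium-positive pixel, the Euclidean
  centre-to-centre distance (µm) to the nearest membrane pixel, signed
  positive inside the cell, negative outside, zero on the membrane. The
  exact nearest boundary pixel comes from the Euclidean distance transform
  with feature indices, so results agree exactly with a brute-force
  all-pairs search.
- **Inside/outside partition**: intensity-weighted. pct_inside sums the net
  deuterium map over positive pixels with signed distance ≥ 0 (membrane
  pixels count as "associated with" the cell) over the total across all
  positive pixels; pct_outside is the complement, and the two always sum to
  100 when defined. With no positive pixels the report is flagged
  "no deuterium" and the percentages are undefined.
- **Spectral extraction**: preprocessed (normalised) spectra at positive
  pixels, tagged with coordinates, signed distance and cell id — the input
  to chemometrics.
- **Z-stacks** are processed slice by slice with a shared exterior mask;
  distances and signal sums are pooled across slices and flagged as 3D.

## Single-EV trapping analytics

The deuteration of a trapped EV is the ratio of the peak intensity at
2140 cm⁻¹ (C–D) to that at 1440 cm⁻¹ (C–H) on the baseline-corrected
spectrum. Peak intensity is read at the bin nearest the nominal position;
this is unbiased on a calibrated axis, whereas a local-maximum search (kept
as an opt-in mode for miscalibrated data) is a max-statistic whose upward
bias of ≈0.5 noise-SD would systematically inflate weak ratios. The ratio is
invariant to rescaling the spectrum and undefined (flagged) when the C–H
reference intensity does not clear the noise floor. Time-course cohorts
(0–24 h incubations) are summarised descriptively — n, mean, SD and a seeded
percentile-bootstrap CI per cohort; inferential testing is left to standard
statistics packages.

## Chemometrics

PCA of the extracted deuterium-positive spectra: mean-centred (no variance
scaling — spectra are already area-normalised), decomposed by SVD, with each
component's sign fixed so its largest-magnitude loading is positive (fully
reproducible scores and loadings). Cohort separation on PC1 is the
standardized mean difference |m_a − m_b| / pooled SD. On synthetic
internalised vs surface-bound spectra the PC1 loading peaks inside the C–D
window and the separation is large (≈7–10); on the phantom-image pipeline
the extracted-pixel separation is much smaller because the planted
interior/surface contrast is milder than in real cohorts.

## The synthetic phantoms

Phantoms provide planted ground truth for every stage. A cell is an ellipse
with nucleus, two nucleoli, lipid droplets and a cytoplasmic protein field;
each component contributes a Gaussian-peak signature (all fingerprint peaks
inside their band windows; lipids/proteins also fill the C–H stretch). To
this linear mixture are added: a shared autofluorescence baseline (cubic in
scaled wavenumber, coefficients (2, 1.5, 0.8, −0.6), plus a broad Gaussian
hump, amplitude 0.3, σ 800 cm⁻¹ — comparable in magnitude to the Raman
bands but far smoother), a shared system background (narrow substrate/buffer
bands at 490, 1050 and 3250 cm⁻¹ plus a flat offset — the part the exterior
subtraction must remove), planted EV pixels (a σ = 25 cm⁻¹ C–D band at
2140 cm⁻¹, scaled per pixel) and i.i.d. Gaussian noise. Boundary pixels
attenuate the cell signatures by 0.5 (a pixel straddling the cell edge sees
half cell, half medium), which also reproduces the observation that
surface-bound deuterium spectra carry proportionally less protein/lipid
signal than internalised ones. EV sites are planted as adjacent 2-pixel
clusters, matching the interpretation of detected signal as EV clusters.

Three uptake cohorts define the comparison experiment: *internalised* (six
deep interior sites, amplitude 2.0, one weak exterior site → planted
inside fraction 92.3%, median depth several µm), *surface_bound* (sites
concentrated on and just outside the membrane → 62.5%, median distance 0)
and *low_uptake* (mostly exterior sites → 25%, negative median). Trap
spectra are built so the noise-free nearest-bin intensity ratio equals the
programmed C–D/C–H ratio exactly.

All randomness flows from one explicit seed; identical parameters and seed
give bit-identical cubes. What the phantoms do **not** emulate: optical
point-spread and confocal sectioning, cosmic rays, detector nonlinearity,
wavenumber calibration error, spatially varying autofluorescence, and the
biological variability of real cells. Green tests therefore demonstrate the
correctness and statistical behaviour of the algorithms under the stated
noise model, not instrument-level performance.

## Numerical choices and degenerate inputs

- Band integrals are exact for piecewise-linear spectra (trapezoid on the
  exact window, endpoints interpolated); Gaussian band areas are accurate to
  ≪1% at 11 cm⁻¹ binning.
- "SNR 5" in the detection experiments means the planted per-pixel band
  signal equals five exterior noise SDs of the detection statistic,
  measured on an EV-free calibration phantom at the same noise level — the
  domain in which the 3σ detector actually operates.
- Distance ties between equidistant membrane pixels are resolved by the
  distance transform's feature choice; the distance value (what is
  reported) is tie-independent.
- Problem sizes: phantoms default to 48×48 pixels × 337 bins; the detection
  experiment uses 20 phantoms plus 20 unlabelled controls; cohort
  comparisons use 3 cells per cohort; PCA experiments 40 spectra per
  cohort. These sizes give stable statistics for all reported quantities.
- Degenerate inputs are first-class: constant maps refuse segmentation,
  empty exteriors refuse subtraction, all-zero spectra are flagged not
  normalised, cohorts of one report missing SDs, and empty deuterium masks
  yield flagged "no deuterium" reports.

## Known limitations

- The 'shape' filter is an open reimplementation (opening + smoothing with a
  flat 500 cm⁻¹ window) of a proprietary background filter; parameter
  correspondence is by construction, not by comparison against the
  commercial implementation.
- Segmentation assumes one dominant, roughly convex cell per image unless
  the multi-cell path is used; touching cells are not split.
- The inside/outside partition is 2D per slice; true 3D membrane distances
  for z-stacks are not computed (slices are pooled instead).
- Bootstrap CIs assume exchangeable spectra within a cohort; trapping
  records from the same EV are not deduplicated.
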