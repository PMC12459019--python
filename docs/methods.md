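# Methods

`vulm` implements a volumetric (3-D + time) ultrasound localization
microscopy (ULM) analysis chain and evaluates it end-to-end on synthetic
data.  This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic experiments do and do not show.

## Processing model

The input is a 4-D stack of beamformed, nonnegative intensity volumes
(depth × lateral × elevation × time) on an isotropic half-wavelength grid
(λ/2 ≈ 98.6 µm for 1540 m/s at 7.81 MHz) at a volume rate of 500 volumes/s
(five compounded plane waves at a 2500 Hz pulse repetition frequency).

**Clutter filtering.** Each batch of 200 volumes is reshaped into a
Casorati matrix (voxels × time) and the largest
`k = round(discard_fraction × batch_size)` singular values are zeroed;
`discard_fraction` defaults to 0.10 (typical working range 0.10–0.15, a
single scalar per run rather than per-image manual tuning, for
reproducibility).  Static tissue is temporally rank-1 and is removed
exactly by k ≥ 1; bubbles that barely move within the 0.4 s batch window
are attenuated together with the tissue, which is the filter's known
slow-flow blind spot.  The magnitude of the reconstruction is taken so
downstream thresholds see nonnegative intensities.  Trailing partial
batches use a proportionally scaled k (never below 1).

**Localization.**  Per batch, intensity is leveled across depth by
dividing every voxel by the mean intensity of its depth plane (a software
time-gain compensation; zero-mean planes are exempted).  Then per volume,
in order: (1) voxels below `noise_floor_fraction` (default 0.035, range
0.03–0.04) of the volume maximum are zeroed; (2) 3×3×3 median filter;
(3) convolution with an isotropic Gaussian matched to the bubble
point-spread function — FWHM of one wavelength = two voxels, hence
σ = 2/(2√(2 ln 2)) ≈ 0.85, applied rounded to 0.8 voxel, kernel truncated
at ±3σ (<10⁻³ mass lost); (4) normalization to maximum 1; (5) white
top-hat with a spherical structuring element of radius 3 voxels (larger
than the PSF footprint, so blobs survive the opening); (6) threshold at
mean + k·std (default k = 2, per-scan range 1–3); (7) 26-connected
components, one intensity-weighted centroid per component, single-voxel
components retained.  Voxel centers sit at `(index + 0.5) × voxel_size`;
axes are ordered (depth, lateral, elevation).

**Tracking.**  Frame-to-frame assignment minimizes total Euclidean
distance (Hungarian algorithm on the rectangular cost matrix) with a gate
of `max_link_distance` = 0.2 mm ≈ (100 mm/s)/(500 vps); no gap closing —
a track that misses one frame terminates.  Tracks shorter than 10 points
are discarded, the rest smoothed per coordinate with a third-order,
nine-point Savitzky–Golay filter (endpoint handling by polynomial fit
within the window).  The short-track rejection is applied before
smoothing; the surviving set is identical either way.  Segment speed is
the distance between consecutive smoothed points times the volume rate.

**Rendering.**  Tracks are rasterized on an isotropic λ/20 grid
(≈9.9 µm): each segment is supersampled at quarter-voxel steps (position
error < ¼ voxel, deterministic) and each voxel a track's polyline
traverses is incremented once per track passage.  The density image is
Gaussian-filtered with σ = 0.8 render-voxels.  The velocity map
accumulates segment speeds per traversed voxel and stores the per-voxel
mean together with a support count; for hemodynamic analysis it is
median-filtered over a 3³ neighborhood **restricted to supported voxels**
(a plain median would drag thin-vessel speeds toward the zero background);
Gaussian smoothing of the velocity map exists for display only.

## Biomarkers

**VD — vascular dropout** (centerline voxels per mm³).  The density image
is binarized (> 0 by default), thinned with a homotopy-preserving 3-D
skeletonization, masked by a region of interest, and the count of skeleton
voxels is divided by the ROI volume.  "Number of vessel centerlines" is
interpreted as skeleton-voxel count, not connected-component count: a
component count would be nearly scale-free and not meaningful per unit
volume.

**BS — bilateral symmetry** (mirror dice).  Pipeline: lateral
translational centering by a bounded integer-shift search (±⅛ of the
lateral extent) maximizing the mirror dice of the preprocessed support — a
center-of-mass shift was rejected because asymmetric vessel brightness
biases it off the anatomical midline; rotational centering about the
depth and elevation axes by a ±10°, 1°-step search maximizing the mirror
dice (rotation about the lateral axis cannot change a bilateral comparison
and is skipped) — both searches are scored on the λ/5 mean-pooled volume
for speed, sequentially per axis with ties resolved to zero, the winning
correction is applied to the full λ/20 volume, and a rotation is kept only
if it improves the full-resolution dice; then mean-pooling 4³ to λ/5,
intensity^0.5 compression, grayscale dilation with a spherical kernel of
radius 0.4λ (2 λ/5-voxels), Gaussian smoothing (σ = 1 voxel, truncated at
2σ so exact zeros stay zero), binarization of nonzero voxels, reflection
across the lateral midline, and dice = 2|A∩B|/(|A|+|B|).  An empty volume
scores 0 and is flagged rather than treated as symmetric.

**LHR — localized hemodynamic reduction.**  Concentric spherical shells
(default outer radii 0.25–4.0 mm in 0.25 mm steps, thickness 0.25 mm)
around a tumoral-side point and its lateral mirror across the midline.
Shell means are taken over supported voxels of the median-filtered
velocity map only; an unsupported shell is reported as missing (NaN), not
zero.  The reported difference is tumoral minus contralateral, so slowed
or missing tumor flow is negative.  Per-shell voxel counts are reported,
since small shells sample few vessels and are noisy.  For a scalar
summary, `hemodynamic_reduction_summary` takes the support-weighted mean
of the per-shell differences over radii ≤ 2.75 mm, with a tumoral shell
that has a supported contralateral counterpart but no samples of its own
counted as full reduction (0 − contralateral mean): an avascular core is
the extreme of hemodynamic reduction, not missing data — while the
per-shell table keeps such shells as NaN.  For synthetic runs
the tumoral point is the lesion center; real data must supply the axial
coordinate (e.g. a fixed depth below the skull surface), which the package
does not infer.

## Synthetic data model

The generator emulates the statistical structure the analysis assumes,
not acoustic physics:

* **Vasculature** — random binary branching trees of straight segments
  with decreasing radii, grown in the left half-domain and duplicated by
  exact reflection about the lateral mid-plane (so the lesion-free
  centerline raster is mirror-symmetric by construction), plus an optional
  dominant midline vessel.  Per-segment centerline speeds are uniform in
  1–30 mm/s (healthy cerebral range).
* **Lesion** — a spherical tumor removes a fraction (default 0.8) of the
  segments whose midpoint lies within the core radius and resamples
  surviving speeds within the periphery into 0.1–0.8 mm/s (tumor-rim
  regime).
* **Bubbles** — per-segment Poisson entries with rates weighted by segment
  length so the expected concurrent count equals `mean_mb_per_volume`;
  each bubble advects along the centerline at the segment speed and exits
  at the segment end.  Each bubble carries one fixed radial offset, drawn
  uniformly within the vessel radius perpendicular to the centerline, so
  the per-frame ground-truth displacement is exactly `speed/volume_rate`
  (an exactness the velocity tests rely on) while renders still show
  finite vessel width.  Per-frame resampled jitter was rejected for this
  reason.
* **Volumes** — each bubble contributes a unit-peak Gaussian blob of
  FWHM λ at its sub-voxel position; a static, spatially smooth, strictly
  positive tissue field (identical in every frame, hence exactly rank-1 in
  time — the minimal model the SVD stage assumes) with amplitude 20× the
  bubble peak; i.i.d. Gaussian sensor noise, clipped at zero.

**Noise level.**  The default `noise_sigma` is 0.01 (1% of the bubble
peak).  This is a consistency requirement, not a convenience: depth
leveling divides by per-depth means that are noise-dominated after
clutter filtering, which pins the leveled noise mean near 1 whatever the
raw σ is; the noise-floor threshold (3%–4% of the volume maximum) can
therefore only remove the noise floor if bubble peaks are ≳30× the noise
mean — the operating regime the published floor fraction presupposes.
In the noise-robustness experiment "SNR" is defined on the intensity
image as 10·log₁₀(blob peak / noise σ), so 10 dB means σ = 0.1 × peak;
that scan uses the detection threshold at k = 3, tuned per scan within
its stated 1–3 range.

## Study sizes

Defaults keep every experiment on one CPU core in minutes: a 48³ λ/2 grid
(≈4.73 mm cube; full field-of-view sizes are supported via config), 800
volumes in the paired control/tumor study, and a bubble density of 15 per
volume — the full-field regime of 60–100 bubbles per volume scaled to this
domain's volume (≈0.09 bubbles/mm³).  The paired study processes the same
healthy network twice (control, and with the default 1 mm-core lesion
applied) from one seed, then compares VD, BS, and the LHR difference
profile.  The lesion is centered on the midpoint of the largest
left-hemisphere vessel: tumor cells are implanted into vascularized
tissue, and anchoring the synthetic lesion to a major vessel keeps the
paired comparison meaningful on networks whose random geometry would
otherwise sometimes leave the lesion in an avascular spot.  Both runs
report their ROI and shells around that same point.

## What passing tests show — and what they do not

The synthetic experiments validate the *pipeline*: exactness of the SVD
contract against an independent eigendecomposition oracle, sub-voxel
centroid accuracy, Hungarian-optimal linking against brute-force
enumeration, speed recovery through the full chain, the biomarker oracles
(cylinder skeletons, constructed dice cases, uniform shell profiles), and
the direction of all three biomarkers under a lesion.  They do not
validate acoustic realism: no speckle, no skull aberration or
attenuation, no depth-dependent PSF, straight-segment vessels rather than
tortuous networks, and bubbles that vanish at segment ends instead of
routing through the tree.  Directional biomarker results on this phantom
therefore demonstrate internal consistency of the method, not in-vivo
performance.

## Known limitations

* Slow flow (0.1–0.8 mm/s) is largely invisible to the 0.4 s SVD window;
  the package reproduces this blindness (it is part of the method) rather
  than correcting it.  No fixed cutoff speed is asserted: the effect is
  characterized empirically per run by comparing recovered track counts
  against the simulator's ground truth (the paired-study tests do exactly
  this for the tumor-rim regime).
* Bubbles closer than a few voxels merge into one connected component;
  no multi-bubble overlap resolution is attempted.
* The bilateral-symmetry rotation search is a bounded grid search scored
  at λ/5 resolution; rotations that only become distinguishable at λ/20
  are not recovered.
* Shell means at small radii rest on few supported voxels; the per-shell
  counts in the report should be consulted before interpreting them.
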