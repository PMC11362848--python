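# Methods

`cortexmap` quantifies immunohistochemistry (IHC) on whole-slide brightfield
images of tumor-adjacent cortex and scores the resulting neuropathology at
cohort level. This note describes the models and procedures, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the design was open.

## Stain model and segmentation

Brightfield IHC slides carry two chromogens: hematoxylin (blue-purple
nuclear counterstain) and DAB (brown immunostain). Per slide, the stain
colors are estimated as the arithmetic mean RGB over a handful of
operator-marked pixels per stain (`estimate_stain_vectors`; ten per stain is
the working default). This per-slide calibration absorbs staining-intensity
variability between slides without any cross-slide normalization model.

**Tissue mask.** A pixel is tissue iff its blue value lies below the
slide-mean blue (tissue absorbs, glass is bright), cleaned by one erosion
followed by one dilation with a disk of radius `tissue_morph_radius_px`
(default 3 px; the radius is an artifact choice). The rule assumes a
meaningful bright-background fraction in the frame; a constant blue channel
is rejected as a degenerate threshold.

**Pixel classification.** For each tissue pixel the angles between its RGB
vector and the two stain reference vectors are computed from the normalized
dot product. A pixel is hematoxylin-stained if its hematoxylin angle is
within `angle_threshold_hema_deg` and no larger than its immunostain angle
(ties break to hematoxylin, a deterministic rule on a measure-zero event);
immunostain symmetrically; otherwise unstained. Non-tissue pixels are
background, so the four labels partition the image. Angles are
scale-invariant, making the classification robust to global intensity
changes. Both angle thresholds default to 15°; they are exposed in
`ClassifierParams` as tunable empirical values, not published constants.

**Blob segmentation.** Nuclei and immunostained particles are segmented by
thresholding a stain projection inside the classified pixels — 30% for the
hematoxylin channel and 40% for the immunostain — then eroding with a disk
of radius 1 px and taking 8-connected component centroids. The projection is
computed in absorbance space: the pixel's (255 − RGB) vector projected onto
the stain's (255 − RGB) direction, min–max normalized over tissue pixels.
The absorbance formulation is deliberate: on a brightfield image the stained
structures are *dark*, so a raw-RGB projection would rank them below the
bright unstained tissue and a superlevel threshold would select background;
in absorbance space the stained structures form the high end of the score,
the 30%/40% thresholds select them, and raising a threshold can only shrink
the segmented set (the count of disk-like blobs is then non-increasing in
the threshold). Touching blobs merge into one component and yield one
centroid; no watershed splitting is attempted, and no color deconvolution
(Ruifrok–Johnston) is used.

## Density maps

Centroids are binned into a per-pixel count map and convolved with a binary
disk kernel (center-in-circle rasterization, radius `kernel_radius_px`,
default 200 px). Dividing by the kernel's physical area — kernel pixel count
× pixel area — yields objects per mm², the only normalization under which a
single isolated object reads as exactly one object per kernel area on its
plateau. Near the frame border, zero padding would bias rim densities low;
by default each pixel's divisor uses only the in-frame kernel fraction.
This renormalization is locally unbiased but not globally mass-conserving:
a centroid sitting exactly one kernel radius from the border over-counts by
roughly 10% in total mass, and the effect vanishes once all centroids lie
two kernel radii or more from the border. Global mass conservation
(mean density × map area = centroid count, to 1e-6 relative) therefore holds
exactly for the plain estimator in the interior-kernel regime, and for the
renormalized estimator whenever no mass lies within two radii of the frame.

Multi-resolution bookkeeping lives in `PipelineScales`. Pixel pitch
(µm/px) is explicit configuration and is never inferred from scanner
metadata: published pipelines of this kind quote working scales (0.5×
primary downsample, 0.0125× map downsample, 73 µm ≈ 5329 µm² map pixels,
200 px ≈ 0.42 mm² kernels) that are not mutually consistent under a single
pitch, so the package treats each scale as an independent, checkable input.
Downsampling to the map grid is block-mean aggregation (partial edge blocks
averaged over their actual extent), which preserves the map-wide mean
density to floating-point precision.

## Serial-section registration

Adjacent sections of one block share a tissue outline up to a small rigid
motion, so tissue-on-background masks serve as the registration backbone.
`rigid_register` minimizes the mean squared difference between the fixed
mask and the warped moving mask, both smoothed with a Gaussian (σ = 2 px) to
create a usable basin. The search is initialized from the mask-centroid
difference combined with the principal-axis angle difference (both
orientations of the 180°-ambiguous axis) plus eight evenly spaced start
rotations in ±20°; the two best starts are refined with Powell's method. The
returned transform is the best candidate encountered *including the
identity*, so the achieved Dice overlap never falls below the unaligned
overlap. On synthetic masks the recovered transforms are accurate to
~0.01° and ~0.01 px, far inside the 0.5°/1 px working tolerance.

Transforms are rotations about the image center plus translation, in (x, y)
pixel coordinates with y pointing down (positive rotation turns x toward y).
Density maps are resampled bilinearly, masks nearest-neighbor; samples drawn
from outside the frame are zero and flagged in an optional validity mask.
Registration runs at the coarse map level (configurable), which is both
faster and well-conditioned since the backbone is a smooth outline.

Annotation polygons (cortex, tumor, slide outline; GeoJSON canonical, a
minimal scanner-XML dialect also readable) become masks by the pixel-center
even-odd rule with pixel centers at integer coordinates, origin top-left.
The cortex pixel table contains one row per map pixel with tissue = 1 and
cortex = 1, in fixed column order (tumor cell, NeuN, Abeta, pTau, Iba1
densities, all per mm²); markers without a slide yield absent columns, never
zeros.

## Cohort scoring

The semiquantitative scales are encoded exactly as used at the microscope:
infiltration low/medium/high with high > 70% nonneuronal cells and medium
operationalized as a nonneuronal fraction in [0.45, 0.70] (the source scale
says only "approximately 1:1"); CERAD 0/A/B/C with the unassigned gap counts
(4, 11–19 per high-power field) mapped to the nearest boundary, preserving
ordinality without inventing categories; ADNC categories AT / T / A /
vascular-only / none from the deposit flags; APP and DAI four-level scales
with the same nearest-boundary gap rule; and a combined severity score as
the sum of the 0–3 Braak-group and CERAD ranks (the staging systems are
"combined" without a published rule; rank addition is monotone in each
component and maps 0 ⇔ both absent). Display percentages round half-up to
integers, matching how such cohorts are reported (22/205 → 11%). Whether
vascular-only cases count as ADNC-positive is exposed as an explicit flag
(`include_vascular`) or an explicit per-record boolean rather than guessed.

Cohen's kappa is computed from the marginal-product chance agreement.
Degenerate cases are defined rather than undefined: perfect agreement is 1
even when both raters are constant (warned); two constant but different
raters return 0 with a warning.

## Statistics

Each variable passes a Shapiro–Wilk gate (normal iff p > .05, α = 0.05
throughout, configurable); normally distributed pairs use Pearson's r,
everything else Kendall's tau-b, whose tie correction suits heavily tied
per-pixel density vectors. Samples beyond 5000 values are thinned to 5000
evenly spaced order statistics before the Shapiro–Wilk test (the W statistic
is calibrated only to that range). Tau-b p-values are exact by enumeration
for small untied samples and tie-adjusted normal approximations otherwise.
Fisher's exact test (two-sided, hypergeometric) handles 2×2 cross tables;
group means use one-way ANOVA followed by pairwise t-tests with Bonferroni
adjustment (adjusted p = min(1, raw p × number of comparisons)). The
numerical kernels delegate to scipy.stats; the module owns the gate logic,
containers and degenerate-input contracts, and the test suite checks tau-b
and Fisher against independent brute-force oracles.

## Synthetic data: what it emulates and what it does not

The generator renders what the analysis consumes: a pale glass background,
a polygonal tissue region with lower blue intensity, hematoxylin-colored
nuclei and DAB-colored particles as anti-aliased disks with Gaussian-soft
edges (centroids analytically known), per-blob color jitter (default σ = 6
per channel, well below the ≈110 RGB distance between the two stains, so
mean blob color always stays nearer its own stain), serial sections related
by small rigid transforms (re-rendered from the moved layout with fresh
jitter), and cortex polygons. Placement is uniform in the tissue polygon by
rejection sampling with at most 30% pairwise disk overlap and 10⁴ attempts
per blob (explicit failure naming the achieved count on saturation); an
optional linear x-gradient biases placement to build spatially coupled
marker pairs, and an optional minimum gap produces well-separated layouts.
One RNG stream per slide, explicitly seeded, makes every fixture
byte-reproducible.

Cohort sampling draws ADNC categories i.i.d. from a stated prevalence map
(defaults follow the published cohort fractions: AT 0.20, T 0.18, A 0.11,
vascular-only 0.03), ages from a clipped normal (67 ± 12 years), and fills
the remaining scores from conditional distributions chosen once from the
same cohort's printed marginals (lobe distribution, CERAD/Braak conditional
frequencies, APP/DAI prevalence, capillary CAA rate ≈ 8%).

Deliberately not emulated: real histology texture, nucleus shape variation
and chromatin structure, stain gradients within a slide, out-of-focus blur,
JPEG artifacts, tissue folds and tears, and non-rigid section distortion.
Passing tests therefore demonstrate that the pipeline recovers known
geometry and statistics under idealized optics — they bound algorithmic
correctness, not performance on real scans, where threshold tuning and the
manual stain marking matter.

## Problem sizes and defaults used in the checked runs

Segmentation recovery runs on a 2048² slide with 500 nuclei and 120
particles (well-separated placement, 3 px minimum gap); registration
recovery on 256² map-level masks over 20 random perturbations (|rot| ≤ 10°,
|t| ≤ 20 px); the end-to-end study on two 1536² serial sections with a
100 px kernel and 1/8 map downsampling, yielding ≈13 000 cortex pixels; the
null calibration of the Kendall test on 500 independent pairs of n = 100.
These sizes exercise every code path at desk scale while keeping the full
suite in the low minutes.

## Known limitations

* Touching blobs merge; counts are biased low in crowded fields unless
  layouts are well separated.
* The blue-mean tissue threshold assumes a substantial bright-background
  fraction in the frame and fails (by design, loudly) on constant images.
* Rigid registration cannot model the non-rigid distortions of real serial
  sections; residual misalignment blurs pixel-level correlations.
* The edge-renormalized density estimator trades global mass conservation
  for local unbiasedness near the frame border (see above).
* Kendall tau-b p-values for large tied tables rely on the asymptotic
  normal approximation.
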