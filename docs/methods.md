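# Methods

## The measurement model

Vascular density is a volume (or area) fraction: contrast-perfused vessel
voxels over tissue-plus-vessel voxels, × 100. Under midpoint thresholding
the vessel mask is a subset of the tissue mask by construction, so "tissue"
always means tissue-plus-vessel. The pipeline assumes: (i) the perfused
placenta produces a trimodal grey-level histogram (air, tissue, contrast);
(ii) slices lie parallel to the chorionic plate with z increasing towards
the basal plate; (iii) only perfused vessels are visible — which is why
vascular fill, measured from histology, gates which blocks enter density
analysis at all.

### Thresholding

The tissue threshold is the arithmetic midpoint of the air and tissue
histogram peaks; the contrast (Microfil) threshold the midpoint of the
tissue and contrast peaks. Peaks are located automatically: the integer
intensity histogram is smoothed with a moving average whose width is 1/64
of the intensity range (odd, minimum 3) and the three most prominent local
maxima are taken, with the lowest intensity of a plateau as its location
(a deterministic surrogate for reading peaks off a histogram by eye).
Fewer than three peaks raises an explicit error and manual thresholds can
be supplied through the config. Applies per volume at both imaging scales.

### Cord-centred geometry

The planar placenta mask is the z-projection of the tissue mask, reduced
to its largest connected component with holes filled (a stand-in for a
manually drawn mask that is robust to isolated noise voxels). From the
cord-insertion pixel, 360 rays at 1° spacing are marched at 0.5 px steps
with nearest-pixel sampling; a ray's edge distance is the radial distance
of the outermost in-mask pixel centre it crosses (the outermost crossing,
so non-convex outlines measure to the placental edge). Every in-mask pixel
is assigned its nearest ray and the normalised distance
100·r/edge(ray), clipped at 100. Discretisation is ±1 px of edge
distance; on a circle of radius R the map is accurate to about 100·1.5/R
units. Block locations measured on photographs use the same formula,
100·d(cord→block)/d(cord→edge through block).

### Skeleton and vessel exclusion

Vessel masks are thinned with Lee's 3D topology-preserving medial-axis
algorithm (26-connectivity). The local radius at a centreline voxel is the
Euclidean distance transform of the vessel mask evaluated there — on
digital cylinders of radius 2–8 this is accurate to well under 0.7 voxels.
Vessels with local radius above 6 voxels (699 µm at the 116.5 µm
whole-placenta voxel) are chorionic-scale and removed: each mask voxel
inherits the radius of its nearest centreline voxel (k-d tree lookup) and
is dropped when that radius exceeds the threshold. Voxel-wise inheritance
(rather than whole-segment removal) was chosen; on constructed thick/thin
cylinders the residual/retained fractions are ≤ 5% / ≥ 95%. A spur-pruning
helper removes endpoint branches shorter than a given length before
topological censuses.

### Density

The radial profile bins tissue voxels by the integer part of their
normalised distance (half-open [b, b+1); bin 99 includes 100; the 2D map
applies column-wise to every slice) and reports mean vascular density per
bin with its voxel count; empty bins carry NaN, never zero. The
voxel-weighted mean over bins equals the global density exactly. Density
maps over arbitrary region labels (default: the 10×10 chunk grid used for
out-of-core processing) follow the same counting rule. Block density uses
a region of interest covering the basal third of the tissue's z-extent
(computed from the tissue bounding range — the deterministic surrogate for
a manually drawn ROI over the villous compartment).

### Chunked processing

Large stacks are tiled in-plane into a 10×10 grid of full-depth labelled
chunks that recombine bit-exactly in any order. Pointwise reductions
(histograms, segmentation, per-region counts) are chunk-exact with no
halo; bounded-support operators use a halo (default 7 voxels, one more
than the radius filter) — the chunked distance transform is exact wherever
the true distance does not exceed the halo. Skeletonisation has unbounded
support and is therefore run on whole volumes, which at the problem sizes
used here fit comfortably in memory; volumes that do not divide evenly end
in short edge tiles rather than being padded.

### Histology

Micrographs are classified into three classes — perfused lumen plus slide
background (contrast agent and the white shrinkage space around it),
unperfused lumen (red cells), villous tissue — by a seed-fixed random
forest over colour and local-texture features (RGB plus Gaussian-smoothed
channels at σ = 1 and 3), trained on a packaged phantom scene generated at
run time; images already rendered in the canonical class colours are
mapped exactly, so label images can be ingested directly and
classification is idempotent on its own renderings. Lumen particles are
8-connected components filtered to area 60–1,000,000 µm² and circularity
4πA/P² in 0.20–1.00 (perimeter from the weighted boundary-step estimator,
circularity capped at 1.0 as digitisation can push compact shapes above
the analytic maximum); the background, which shares the perfused class, is
removed as the border-touching component and would in any case fail the
filters. Vascular fill is 100 × Σ(perfused areas above cutoff) / Σ(all
lumen areas above cutoff) — undefined (NaN, excluded) when nothing
qualifies — at cutoffs of 10,000 µm² (whole-placenta-relevant vessels,
all micrographs) and 200 µm² (block-relevant vessels, basal-half
micrographs only). Histological vascular density is 100 × Σ(lumen areas) /
(villous area + Σ lumen areas). Blocks with fill below 75% at the 200 µm²
cutoff are excluded (non-strict at exactly 75%). The fill and density
formulas are stated here as this package's definitions, chosen to match
the semantics of per-block fill/density spreadsheets.

### Statistics

Spearman rank correlation with midrank ties (two-sided p via the
t-approximation); tie-corrected Kruskal–Wallis H with Dunn's pairwise z
using the tie-corrected pooled variance and Bonferroni adjustment over all
unordered pairs; descriptives as mean ± sample (n−1) SD, range, median and
linear-interpolation IQR. Significance at α = 0.05. Calibration is part of
the test surface: the Kruskal–Wallis type-I error under a simulated
two-group null (n = 20 each, 1,000 reps) must lie in 5% ± 1.5 pp, and
Spearman p-values under independence are uniform (KS test at n = 50; at
much smaller n the discreteness of ranks makes exact uniformity fail by
construction).

## The phantoms and what they do (not) show

The 3D phantom is a tissue disc (default radius 56 voxels, thickness 28,
in a 128×128×40 grid at 116.5 µm/voxel) holding vessel trees grown by
recursive binary branching with fixed per-generation radius taper
(default root radius 1.6 voxels, taper 0.9, 3 generations, segment length
shrinking by 0.75) and midpoint-displaced segments rendered as finite
cylinders. Defaults emulate villous-calibre vessels at a few percent
volume fraction; the number of trees for a target fraction comes from the
analytic tree volume (overlap and edge clipping make the realised fraction
some 15–20% lower, which is immaterial because all checks compare against
the rendered ground truth). Intensities default to (30, 120, 240) with
additive Gaussian noise of SD 10% of the tissue–air gap, clipped to the
16-bit range — modes stay separable and, at these levels, essentially no
voxels cross a threshold. Unperfused terminal segments are rendered at
tissue intensity, the physical meaning of incomplete contrast filling.

Tree roots are sown on the chorionic face with stratified (jittered)
inverse-CDF radial placement in a disc dilated by the expected lateral
tree extent, so that after clipping, coverage is statistically stationary
to the edge; `density_gradient` g thins placement linearly as
(1 − g·r/R). Stratification makes the realised radial density a
controlled property of the generator rather than a Poisson-noisy one.
Near the cord the annuli of the 100-bin profile are smaller than a tree
footprint, so single realisations there are dominated by whether a trunk
happens to fall in a tiny region; profile-flatness checks therefore
consider bins whose tissue count reaches at least a third of the median
bin count, alongside the interior bins 5–95.

Ground truth is exact by construction: masks as rendered, centreline
voxels with their segment radii, and per-bin densities from the analytic
cord-to-edge normalisation of the disc. Because one pixel of ray-edge
discretisation at disc radius ~56 px moves voxels by about two of the 100
bins, per-bin density accuracy is assessed under a shared spatial binning
(the pipeline's own distance map applied to measured and ground-truth
masks), which isolates density estimation from geometric discretisation;
the geometry itself is validated separately against analytic circles and
fine-ray-marching oracles.

The 2D phantom places elliptical lumens inside elliptical villous
profiles (lumens carve out of the villus, keeping classes disjoint;
straddling or cross-class-overlapping ellipses are rejected), perfused
lumens with a contrast-coloured core inside a white shrinkage rim, on a
white background with mild colour noise.

What the phantoms do **not** emulate: X-ray physics (beam hardening, ring
artefacts, partial-volume blur), real tree topology and anastomoses,
haemodynamically realistic radii (no Murray's law), stain variability,
red-cell texture, or touching/overlapping lumens. Passing tests therefore
demonstrate correctness of the measurement chain under the assumed image
model, not robustness to scanner or staining artefacts; on real data the
manual steps these surrogates replace (mask drawing, peak reading,
classifier training) would re-introduce operator variance.

## Problem sizes and numerical choices

Test and acceptance runs use volumes of at most 128×128×40 (recovery, at
ground-truth fills of 2/5/10%, five seeds each) and 256×256×24
(homogeneous null runs, 20 seeds, 60 non-overlapping blocks of 16×16
in-plane voxels per run) — sizes chosen so the full suite runs in minutes
while keeping every bin and block well populated. All randomness flows
through explicit integer seeds (`numpy.random.default_rng`); phantom
generation, the classifier and the pipeline are bit-reproducible for a
fixed seed. Ties and plateaus break deterministically (lowest intensity;
midranks). Degenerate inputs raise typed errors (`ConfigError`,
`DataError`, `ThresholdDetectionError`) that the CLI maps to exit codes
2/3.

## Known limitations

* Radius-based exclusion inherits radii voxel-wise from the nearest
  centreline voxel; near junctions of thick and thin vessels the
  attribution is approximate.
* The 360-ray normalised distance map quantises direction to 1° and edges
  to pixel centres; per-pixel values are only meaningful to ~1 px of edge
  distance, which matters when 100 bins span a small radius.
* The histology classifier is trained on phantom colours; real H&E
  sections would need retraining or direct ingestion of label images
  (supported).
* Skeletonisation is whole-volume; genuinely out-of-core volumes would
  need a stitched thinning scheme, which is not implemented.
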