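# placvasc

Multiscale quantification of feto-placental vascular density from
contrast-perfused imaging of the human placenta.

Whether villous vascular density follows a reproducible spatial pattern
between the umbilical cord insertion and the placental edge is a
long-standing question in placental biology: pathologies such as
pre-eclampsia and fetal growth restriction alter villous vascularisation,
so the normal spatial baseline matters. This package implements, as a
tested and reusable pipeline, an analysis of that question across three
scales of observation of Microfil-perfused term placentas:

* **whole-placenta micro-CT** (isotropic 116.5 µm voxels): histogram-midpoint
  segmentation of tissue and contrast-filled vessels, 3D thinning to a
  vascular skeleton with per-voxel radius from the Euclidean distance
  transform, exclusion of chorionic-scale vessels (radius > 6 voxels
  ≈ 700 µm), and the mean vascular density in each of 100 normalised
  distance bins radiating from the cord insertion to the edge;
* **block micro-CT** (13.5 µm voxels): villous vascular density of
  full-depth tissue blocks, measured in a region of interest over the
  basal third of the tissue, as vessel volume over tissue-plus-vessel
  volume;
* **histology** (H&E micrographs at known µm/pixel): three-class pixel
  classification (perfused lumen + background, unperfused lumen, villous
  tissue), particle analysis of lumens with area 60–1,000,000 µm² and
  circularity 4πA/P² in 0.20–1.00, **vascular fill** (perfused share of
  lumen area above a size cutoff — 10,000 µm² for whole-placenta scale,
  200 µm² for block scale) as perfusion quality control with a ≥ 75% fill
  inclusion rule, and **vascular density** as lumen area over
  villous-plus-lumen area.

Spatial position is always the *normalised location*: the distance from
the cord insertion divided by the cord-to-edge distance through the same
point, × 100 (0 = cord, 100 = edge), measured through 360 rays for images
and from chorionic-plate photographs for blocks. The statistical layer is
rank-based: Spearman correlation of density against location, and
Kruskal–Wallis across placentas with Dunn's pairwise post-hoc under a
Bonferroni correction (α = 0.05).

Because the original specimens are not deposited, the package ships
first-class synthetic phantoms with voxel/pixel-exact ground truth — a
tissue disc containing tapering branching vessel trees with controllable
perfusion fraction and radial density gradient, and micrograph scenes of
elliptical lumens inside villous profiles — on which every step of the
pipeline is validated.

## Worked example

The numbered scripts under `analysis/` run the three tracks over the
synthetic cohort and write their tables under `results/`:

```sh
python analysis/01_generate_phantoms.py   # phantom stacks + micrographs
python analysis/02_whole_placenta.py      # radial density profiles
python analysis/03_block_density.py       # block density vs location (null)
python analysis/04_histology.py           # particle analysis + fill QC
python analysis/05_stats.py               # rank statistics + calibration
```

A run of steps 02–03 prints, per phantom placenta and over twenty
homogeneous-phantom runs:

```
P0: global density 4.36% (truth 4.36%), radial trend r_s=+0.099 (p=0.35), 1567 skeleton voxels
P1: global density 4.29% (truth 4.29%), radial trend r_s=-0.159 (p=0.13), 1569 skeleton voxels
P2: global density 4.41% (truth 4.41%), radial trend r_s=-0.212 (p=0.04), 1571 skeleton voxels
20/20 runs show no density-location correlation (|r_s| < 0.3 and p > 0.05)
median |r_s| = 0.087
radial profile flatness: mean range 0.55 pp vs Monte-Carlo SD 0.47 pp (flat if range <= 2x SD)
```

The measured global densities match the rendered ground truth, and
spatially homogeneous phantoms yield flat radial profiles and
non-significant density–location correlations — the synthetic analogue of
finding no consistent spatial pattern of villous vascular density.

The same machinery is scriptable as a CLI over YAML configs for real
TIFF slice stacks and micrograph manifests:

```sh
placvasc whole     -c config.yaml   # profile.csv, skeleton.csv, density_map.csv
placvasc block     -c config.yaml   # blocks_density.csv
placvasc histology -c config.yaml   # particles.csv, histology_blocks.csv
placvasc stats     -c config.yaml   # stats_report.json
```

Exit codes: 0 success, 2 config error, 3 data error; every run writes a
provenance record (config hash, seed, version).

## Layout

```
src/placvasc/     stackio, segmentation, geometry, skeleton, density,
                  histology, stats, phantom, experiments, pipeline, cli
analysis/         numbered narrative drivers over the library
tests/            pytest suite (unit, property and acceptance tests)
scripts/          acceptance.py
docs/methods.md   models, parameters, numerical choices, limitations
```
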