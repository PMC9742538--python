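# Methods

## Imaging geometry and conventions

A volume is indexed `(y, z, x)` = (B-scan index, axial depth row, lateral
column); row 0 of every B-scan is nearest the probe. The default
`VoxelGeometry` is 12 μm between B-scans, 2 μm laterally within a B-scan
and 1.45 μm axially — the 1.45 μm value is assigned to the axial axis
because it is the only one consistent with the micrometre-scale depth
resolution of spectral-domain OCT. Biofilms are grown on the bottom of a
polystyrene well and imaged through PBS, so in image coordinates the
biofilm sits *above* (smaller row index than) the bright plastic band;
"below the surface" always means larger row index.

Intensities are kept on their native scale by the reader and max-normalised
to [0, 1] per volume before segmentation, decoupling thresholds from bit
depth. Thickness is reported in μm and is by construction an integer
multiple of the axial voxel size.

## The quantification pipeline

Per volume: (1) 3×3 median filter per B-scan with edge replication
(`scipy.ndimage.median_filter`, `mode="nearest"`; zero padding would darken
borders); (2) two thresholds from three-class Otsu on the pooled filtered
histogram (256 bins), shared by all B-scans of the volume so the
segmentation is consistent across the scan — fixed thresholds are available
for full reproducibility across instruments; (3) per-voxel labelling:
background < `t_low` ≤ biofilm < `t_high` ≤ surface; (4) per A-scan, the
surface is the longest run of surface voxels with length ≥
`min_surface_run` (default 2), ties resolved toward the deeper run — both
choices suppress thin bright speckle above the plate; (5) biofilm voxels
below the *bottom* of the selected run are reflections and are relabelled
background; A-scans with no detected surface lose all biofilm voxels and
contribute zero thickness; (6) thickness per A-scan = biofilm voxel count ×
axial resolution, and the per-well value is the mean over **all** lateral
points, zeros included — undetected-surface columns dilute the mean by
design, with `valid_fraction` reported as a diagnostic. Whether "below the
surface" is measured from the run's top or bottom is an open choice; the
bottom is used so genuine biofilm lying between a speckle-split surface run
is never discarded.

Replicate wells are summarised as grand mean ± sample sd (n−1) over
per-well means — one value per well is the replicate unit. Welch's t-test
is implemented from its formulas (statistic, Welch–Satterthwaite df,
two-sided p via the regularised incomplete beta) because the test itself is
part of the validated surface; `scipy.stats.ttest_ind(equal_var=False)`
serves as an independent oracle in the tests only. Degenerate zero-variance
inputs return t = 0, p = 1 (equal means) or t = ±∞, p = 0, flagged.

### Blank wells

A blank (PBS-only) scan contains two intensity classes, not three. A
three-class Otsu split is then undefined: on exactly two distinct values
the threshold pair collapses onto their midpoint, the biofilm class is
empty, a warning is emitted, and the well quantifies to 0 μm. Constant
images are rejected outright.

## The phantom generator

`simulate_volume` emulates the imaged scene, not OCT physics: a bright
surface band (default 12 rows starting at row 160 of 256) with optional
per-column rounded tilt; a biofilm layer of planted thickness stacked
gap-free on the probe side of the band; mean class intensities
(0.05, 0.45, 0.90) for background/biofilm/surface — well-ordered and
roughly matching the contrast of plastic vs biofilm vs buffer;
multiplicative gamma speckle with mean 1 (shape 50 ⇒ sd ≈ 14%, a standard
first-order surrogate for fully developed OCT speckle); and sub-surface
reflection blobs (biofilm-level intensity, 4–8 rows × 3–9 columns, ≥2 rows
below the band so the median filter cannot bridge them) under a stated
fraction of columns. There is no attenuation profile, PSF convolution or
refraction; a green recovery test therefore establishes correctness of the
segmentation logic on speckled three-class scenes, not robustness to
depth-dependent signal loss or real instrument artifacts.

Thickness fields: flat, linear ramp in x, or a moving-average-smoothed
Gaussian rough field (mean, amplitude, correlation length in columns).
Fields are quantised to whole voxels by round-half-up, and ground truth is
stored *after* quantisation so exact per-column assertions are well-posed.
Same spec and seed give bit-identical volumes.

## Exactness and the median filter

In the noiseless limit, segmentation and surface detection are
threshold-exact, so the only stage that can move a boundary is the median
filter. A 3×3 median leaves the scene invariant iff the label boundaries
have lateral steps ≤ 1 row per column and no feature of width 1: flat
slabs (any modest tilt) and untilted ramps qualify and are recovered
exactly at 100% of columns. A quantised rough profile always contains
single-column extrema, which the median erodes by one voxel (and a tilted
ramp forms the same width-1 notch wherever a thickness step lands next to
a tilt step) — so per-column exactness for arbitrary fields is only
well-posed with the identity kernel (`median_kernel=1`), which the
exactness tests use for those cases; a separate test pins the bounded,
near-unbiased error of rough fields under kernel 3. This is an inherent
property of median smoothing, not an implementation artifact.

With speckle (shape 50) and 10% artifact columns, the recovered mean over
128×128 A-scans sits within ~0.02 μm of the planted mean across seeds,
far inside the ±2-voxel (±2.9 μm) acceptance band.

## DE-table filtering

The filter classifies genes as up/down by a symmetric log2FC cutoff,
optionally intersected with padj < cutoff when the column exists. Published
tables print rounded values; with a declared printed precision the
comparison is made on values rounded to that precision with an inclusive
boundary (a printed 2.0 passes cutoff 2) — the only semantics under which
a printed table reproduces its own row counts. The packaged table
(38 genes, biofilm vs planktonic at 48 h) prints no padj column; its rows
are stated to have passed padj < 0.05 upstream, which cannot be re-verified
row-wise from the printed values.

## Known limitations

- No refraction or attenuation correction: absolute thickness of dense or
  high-index biofilms would be biased on real data.
- Auto-thresholds are per-volume; comparing volumes with very different
  dynamic ranges is better done with fixed thresholds.
- The surface must be the longest high-intensity run per A-scan; scans
  with a second strong reflector below the plate would need
  `min_surface_run`/threshold tuning.
- Multi-group comparisons (ANOVA, rank tests) are out of scope; inputs
  with more than two groups should go to a general statistics package.
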