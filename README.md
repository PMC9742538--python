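# biofilmoct

Quantification of bacterial biofilm thickness from optical coherence
tomography (OCT) volume scans of microtiter-plate wells, with a synthetic
phantom generator for validation, the standard plate-assay formulas, and a
differential-expression table filter. Written for microbiologists measuring
biofilm formation of staphylococci (and other plate-grown organisms) with
spectral-domain OCT.

## The measurement

An OCT volume scan of a well is a stack of B-scans, each a grid of A-scans
(depth profiles). Three intensity classes make up the scene: low-intensity
background (PBS), a medium-intensity biofilm layer, and the high-intensity
polystyrene surface it grows on. Thickness is computed per A-scan:

1. **median filter** each B-scan (3×3, edge-replicated) to suppress speckle;
2. **segment** voxels into background / biofilm / surface by two intensity
   thresholds, found per volume by three-class Otsu on the pooled filtered
   histogram (or fixed in `SegmentationParams`);
3. **detect the plastic surface** per A-scan as the longest run of
   surface-class voxels (ties go to the deeper run, suppressing bright
   speckle above the plate);
4. **remove sub-surface artifacts**: medium-intensity voxels below the
   surface run are reflections, not biofilm, and are relabeled background;
5. **thickness** per A-scan = (biofilm voxel count) × axial resolution
   (1.45 μm for the default geometry); the per-well value is the mean over
   *all* lateral points of the scan, zeros included.

Conditions (strains, medium supplements) are summarised as grand mean ± sd
over replicate-well means and compared with Welch's unequal-variance
*t*-test, implemented from its defining formulas.

Because real well scans are rarely shareable, `PhantomSpec` /
`simulate_volume` build phantoms with a planted, voxel-quantised thickness
field (flat, ramp or rough), a tilted bright surface band, gamma speckle
and sub-surface reflection blobs — so the whole pipeline can be validated
against exact ground truth.

## Worked example

```python
from biofilmoct import PhantomSpec, simulate_volume, quantify_volume, mean_thickness

spec = PhantomSpec(shape=(32, 256, 128), thickness_params={"T": 91.4},
                   speckle_shape=50.0, artifact_rate=0.1, seed=42)
volume, truth = simulate_volume(spec)
result = quantify_volume(volume)
print(f"planted   {truth.thickness_map_um.mean():.3f} µm")
print(f"recovered {mean_thickness(result.thickness):.3f} µm")
```

prints

```
planted   91.350 µm
recovered 91.362 µm
```

a 91.4 μm slab is quantised to 63 axial voxels (91.35 μm), and the pipeline
recovers the planted mean to ~0.01 μm despite 14% multiplicative speckle and
reflection artifacts under 10% of the A-scans. The scripts in `examples/`
walk through phantom quantification, replicate/condition comparison, the
assay formulas and the DE-table filter; each prints the numbers above or
their analogues with a line of interpretation.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates flat-slab phantoms planted at the two reference mean
thicknesses (91.4 and 46.3 μm) under speckle and artifacts, runs the full
pipeline over five seeds × 128×128 A-scans each, and writes the recovered
mean thickness per target as JSON.
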