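"""Simulate a speckled OCT phantom and quantify its biofilm thickness.

Builds a flat 63-voxel (91.35 μm) biofilm slab on a plastic surface, adds
multiplicative speckle and sub-surface reflection artifacts, runs the full
pipeline and compares recovered to planted thickness.
"""

import numpy as np

from biofilmoct import (
    PhantomSpec,
    mean_thickness,
    quantify_volume,
    simulate_volume,
    write_thickness_map,
)

spec = PhantomSpec(
    shape=(32, 256, 128),          # 32 B-scans × 256 axial rows × 128 A-scans
    thickness_params={"T": 91.4},  # μm; quantised to 63 voxels = 91.35 μm
    speckle_shape=50.0,            # gamma speckle, sd ≈ 14% of the mean
    artifact_rate=0.1,             # reflection blobs under 10% of columns
    seed=42,
)
volume, truth = simulate_volume(spec)
result = quantify_volume(volume)

planted = truth.thickness_map_um.mean()
recovered = mean_thickness(result.thickness)
exact = np.mean(result.thickness.values == truth.thickness_map_um)

print(f"planted mean thickness   : {planted:8.3f} μm")
print(f"recovered mean thickness : {recovered:8.3f} μm")
print(f"absolute error           : {abs(recovered - planted):8.3f} μm "
      f"(tolerance ±2 voxels = ±2.90 μm)")
print(f"columns recovered exactly: {exact:8.1%}")
print(f"Otsu thresholds (t_low, t_high): "
      f"({result.thresholds[0]:.3f}, {result.thresholds[1]:.3f})")

write_thickness_map(result.thickness, "phantom_thickness.tsv")
print("thickness map written to phantom_thickness.tsv (+ .json summary)")
# The recovered mean is the per-well statistic a plate experiment reports;
# sub-voxel mean error despite speckle shows segmentation + artifact removal
# are unbiased on this scene.
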