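"""Voxel geometry of an OCT volume scan.

Axis convention used throughout the package: a volume is indexed
``(y, z, x)`` = (B-scan index, axial depth row, lateral column).  Row 0 of
every B-scan page is nearest the probe; depth increases with the row index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical size of one voxel, in micrometres.

    Parameters
    ----------
    axial_res
        μm per voxel along depth (z, axis 1 of the volume).
    lateral_res_x
        μm per voxel along the B-scan width (x, axis 2).
    lateral_res_y
        μm between adjacent B-scans (y, axis 0).
    """

    axial_res: float
    lateral_res_x: float
    lateral_res_y: float

    def __post_init__(self) -> None:
        for name in ("axial_res", "lateral_res_x", "lateral_res_y"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive and finite, got {v!r}")


#: Geometry of the spectral-domain OCT instrument this package was written
#: around: 12 μm B-scan spacing, 2 μm lateral, 1.45 μm axial.
DEFAULT_GEOMETRY = VoxelGeometry(axial_res=1.45, lateral_res_x=2.0, lateral_res_y=12.0)
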