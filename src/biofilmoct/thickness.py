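"""Thickness maps and condition summaries.

Thickness is counted per A-scan: the number of biofilm voxels in the column
(after sub-surface cleanup) times the axial voxel size in μm.  The mean over
a scan includes every lateral point — zero-thickness columns dilute the mean
by design, because the reported per-well value averages the whole scanned
area, blanks included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import VoxelGeometry
from .segmentation import BIOFILM, LabelVolume, SurfaceModel


@dataclass
class ThicknessMap:
    """Biofilm thickness in μm on the lateral (y, x) grid of a volume.

    Values are integer multiples of ``geometry.axial_res`` by construction.
    ``surface_found`` flags columns whose plastic surface was detected;
    undetected columns carry thickness 0.
    """

    values: np.ndarray
    geometry: VoxelGeometry
    surface_found: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        found = np.asarray(self.surface_found, dtype=bool)
        if values.ndim != 2 or values.size == 0:
            raise ValueError(f"thickness values must be a non-empty 2D grid, got {values.shape}")
        if found.shape != values.shape:
            raise ValueError("surface_found grid must match values shape")
        if not np.all(np.isfinite(values)) or values.min() < 0:
            raise ValueError("thickness values must be finite and >= 0")
        self.values = values
        self.surface_found = found

    @property
    def valid_fraction(self) -> float:
        """Fraction of lateral points with a detected surface (diagnostic)."""
        return float(np.mean(self.surface_found))


@dataclass
class ConditionSummary:
    """Replicate-level summary of one growth condition (strain or supplement).

    One replicate = one well = one thickness map; its mean thickness is the
    replicate value.  ``grand_mean`` is the arithmetic mean over replicates
    and ``sd`` the sample standard deviation (n−1 denominator), matching the
    mean ± sd convention for per-condition biofilm thickness.
    """

    condition_label: str
    replicate_means: list[float]
    grand_mean: float
    sd: float


def column_thickness(labels: LabelVolume, surface: SurfaceModel,
                     geometry: VoxelGeometry) -> ThicknessMap:
    """Per-A-scan biofilm thickness from a cleaned label volume.

    Requires labels already passed through ``remove_subsurface``: a column
    flagged NOT_FOUND that still carries biofilm voxels violates that
    contract and is rejected rather than silently zeroed.
    """
    lab = labels.labels
    ny, nz, nx = lab.shape
    if surface.surface_row.shape != (ny, nx):
        raise ValueError(
            f"surface grid {surface.surface_row.shape} does not match label volume ({ny}, {nx})"
        )
    counts = np.sum(lab == BIOFILM, axis=1)  # (y, x) biofilm voxels per column
    found = surface.found
    stray = (~found) & (counts > 0)
    if stray.any():
        y, x = np.argwhere(stray)[0]
        raise ValueError(
            f"column (y={y}, x={x}) has no detected surface but {counts[y, x]} biofilm "
            "voxels; run remove_subsurface before column_thickness"
        )
    values = counts * geometry.axial_res
    return ThicknessMap(values=values, geometry=geometry, surface_found=found)


def mean_thickness(tmap: ThicknessMap) -> float:
    """Arithmetic mean thickness over ALL lateral points, zeros included."""
    if tmap.values.size == 0:
        raise ValueError("cannot average an empty thickness map")
    return float(np.mean(tmap.values))


def summarize_condition(maps: list[ThicknessMap], label: str) -> ConditionSummary:
    """Condition summary across replicate wells (>= 2 required for a sd)."""
    if len(maps) < 2:
        raise ValueError(f"need >= 2 replicate maps for a condition summary, got {len(maps)}")
    means = [mean_thickness(m) for m in maps]
    grand = float(np.mean(means))
    sd = float(np.std(means, ddof=1))
    if not math.isfinite(sd):
        raise ValueError("replicate means produced a non-finite sd")
    return ConditionSummary(
        condition_label=label, replicate_means=means, grand_mean=grand, sd=sd
    )
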