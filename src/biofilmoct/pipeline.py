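"""End-to-end quantification: OCT volume in, thickness map out.

Stages, in order: per-volume max normalisation; per-B-scan median filter;
one pair of 3-class Otsu thresholds pooled over the filtered volume (or the
fixed pair from the params); per-voxel segmentation; per-A-scan surface
detection; sub-surface biofilm removal; voxel counting times axial
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .oct_io import OCTVolume
from .segmentation import (
    LabelVolume,
    SegmentationParams,
    SurfaceModel,
    compute_thresholds,
    detect_surface,
    median_filter_bscan,
    normalize_volume,
    remove_subsurface,
    segment_classes,
)
from .thickness import ThicknessMap, column_thickness


@dataclass
class PipelineResult:
    """Everything the pipeline produced, for inspection and provenance."""

    thickness: ThicknessMap
    labels: LabelVolume
    surface: SurfaceModel
    thresholds: tuple[float, float]
    params: SegmentationParams


def quantify_volume(volume: OCTVolume, params: SegmentationParams | None = None) -> PipelineResult:
    """Run the full thickness pipeline on one OCT volume."""
    if params is None:
        params = SegmentationParams()

    normalized = normalize_volume(volume.intensities)
    filtered = np.stack(
        [median_filter_bscan(normalized[y], params.median_kernel)
         for y in range(normalized.shape[0])],
        axis=0,
    )

    if params.auto_threshold:
        thresholds = compute_thresholds(filtered)
    else:
        thresholds = (params.t_low, params.t_high)

    labels = LabelVolume(labels=np.stack(
        [segment_classes(filtered[y], params, thresholds=thresholds)
         for y in range(filtered.shape[0])],
        axis=0,
    ))

    surface = detect_surface(labels, params)
    cleaned = remove_subsurface(labels, surface)
    tmap = column_thickness(cleaned, surface, volume.geometry)
    return PipelineResult(thickness=tmap, labels=cleaned, surface=surface,
                          thresholds=thresholds, params=params)
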