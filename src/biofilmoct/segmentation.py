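"""Per-B-scan processing: median filter, three-class intensity segmentation,
plastic-surface detection and sub-surface artifact removal.

The scene this module assumes: biofilms grown on the bottom of a polystyrene
well and imaged through PBS from above.  In image coordinates the probe is at
axial row 0, so the biofilm layer (medium intensity) sits ABOVE the bright
plastic surface band, i.e. at smaller row indices; "below the plastic
surface" means larger row indices.  Medium-intensity pixels below the surface
are reflection artifacts and are removed before thickness is counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import median_filter
from skimage.filters import threshold_multiotsu

# Label codes of the three-class partition.
BACKGROUND = 0
BIOFILM = 1
SURFACE = 2

#: Sentinel for lateral columns where no plastic surface was detected.
NOT_FOUND = -1


@dataclass
class SegmentationParams:
    """Tunable knobs of the segmentation stage.

    ``t_low``/``t_high`` are thresholds on max-normalised intensity in
    (0, 1): pixels below ``t_low`` are background, pixels at or above
    ``t_high`` are plastic surface, the band between is biofilm.  With
    ``auto_threshold`` the two thresholds are derived per volume by
    three-class Otsu on the pooled filtered histogram (256 bins) and the
    fixed values are ignored.
    """

    median_kernel: int = 3
    auto_threshold: bool = True
    t_low: float = 0.2
    t_high: float = 0.7
    min_surface_run: int = 2

    def __post_init__(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError(f"median_kernel must be odd and >= 1, got {self.median_kernel}")
        if self.min_surface_run < 1:
            raise ValueError(f"min_surface_run must be >= 1, got {self.min_surface_run}")
        if not self.auto_threshold:
            if not (0.0 < self.t_low < self.t_high < 1.0):
                raise ValueError(
                    f"fixed thresholds need 0 < t_low < t_high < 1, got "
                    f"t_low={self.t_low}, t_high={self.t_high}"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SegmentationParams":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        known = {k: cfg[k] for k in
                 ("median_kernel", "auto_threshold", "t_low", "t_high", "min_surface_run")
                 if k in cfg}
        return cls(**known)

    def to_dict(self) -> dict:
        return {
            "median_kernel": self.median_kernel,
            "auto_threshold": self.auto_threshold,
            "t_low": self.t_low,
            "t_high": self.t_high,
            "min_surface_run": self.min_surface_run,
        }


@dataclass
class LabelVolume:
    """Per-voxel class labels aligned to a source OCT volume.

    Every voxel carries exactly one of {BACKGROUND, BIOFILM, SURFACE}.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {labels.shape}")
        bad = ~np.isin(labels, (BACKGROUND, BIOFILM, SURFACE))
        if bad.any():
            raise ValueError("labels contain values outside {BACKGROUND, BIOFILM, SURFACE}")
        self.labels = labels.astype(np.int8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def class_counts(self) -> dict[int, int]:
        return {c: int(np.sum(self.labels == c)) for c in (BACKGROUND, BIOFILM, SURFACE)}


@dataclass
class SurfaceModel:
    """Axial position of the plastic surface per lateral (y, x) position.

    ``surface_row`` is the topmost (shallowest) voxel of the selected
    surface run; ``surface_bottom`` its deepest voxel.  Columns with no
    qualifying run hold the sentinel ``NOT_FOUND`` in both grids.
    """

    surface_row: np.ndarray
    surface_bottom: np.ndarray

    def __post_init__(self) -> None:
        top = np.asarray(self.surface_row, dtype=int)
        bot = np.asarray(self.surface_bottom, dtype=int)
        if top.shape != bot.shape or top.ndim != 2:
            raise ValueError("surface_row and surface_bottom must be equal-shape 2D grids")
        found = top != NOT_FOUND
        if np.any(bot[found] < top[found]):
            raise ValueError("surface_bottom must be >= surface_row where defined")
        self.surface_row = top
        self.surface_bottom = bot

    @property
    def found(self) -> np.ndarray:
        return self.surface_row != NOT_FOUND


def normalize_volume(intensities: np.ndarray) -> np.ndarray:
    """Max-normalise a volume to [0, 1] to decouple thresholds from bit depth."""
    arr = np.asarray(intensities, dtype=float)
    peak = arr.max()
    if peak <= 0:
        return np.zeros_like(arr)
    return arr / peak


def median_filter_bscan(bscan: np.ndarray, kernel: int) -> np.ndarray:
    """Median-filter one B-scan with a kernel×kernel window, edge replication.

    kernel=1 is the identity.  Delegates to ``scipy.ndimage.median_filter``
    with ``mode="nearest"`` (replicate border pixels, avoiding darkened
    edges that zero padding would cause).
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"median kernel must be odd and >= 1, got {kernel}")
    bscan = np.asarray(bscan, dtype=float)
    if bscan.ndim != 2 or bscan.size == 0:
        raise ValueError(f"bscan must be a non-empty 2D array, got shape {bscan.shape}")
    if kernel == 1:
        return bscan.copy()
    return median_filter(bscan, size=kernel, mode="nearest")


def compute_thresholds(filtered: np.ndarray) -> tuple[float, float]:
    """Two 3-class Otsu thresholds from a pooled normalised histogram (256 bins).

    Raises on constant input, where any split is undefined.  Exactly two
    distinct values is the blank-well scene (background + plastic, no
    biofilm): both thresholds collapse onto the midpoint so the medium class
    is empty and the scan quantifies to zero thickness.
    """
    arr = np.asarray(filtered, dtype=float)
    unique = np.unique(arr)
    if unique.size < 2:
        raise ValueError(
            "auto threshold needs a non-constant image; "
            f"all pixels equal {unique[0] if unique.size else 'nothing'} — is this a blank scan?"
        )
    if unique.size == 2:
        warnings.warn(
            "only two intensity classes present (blank well?); "
            "labelling them background/surface with an empty biofilm class",
            stacklevel=2,
        )
        mid = float(unique.mean())
        return mid, mid
    t_low, t_high = threshold_multiotsu(arr, classes=3, nbins=256)
    return float(t_low), float(t_high)


def segment_classes(bscan: np.ndarray, params: SegmentationParams,
                    thresholds: tuple[float, float] | None = None) -> np.ndarray:
    """Three-class segmentation of one normalised B-scan.

    Pixel p -> BACKGROUND if p < t_low, BIOFILM if t_low <= p < t_high,
    SURFACE if p >= t_high.  ``thresholds`` overrides the params (used by
    the pipeline to share one pooled Otsu pair across all B-scans of a
    volume); otherwise fixed params or per-image Otsu apply.
    """
    arr = np.asarray(bscan, dtype=float)
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("segment_classes expects normalised intensities in [0, 1]")
    if thresholds is not None:
        t_low, t_high = thresholds
    elif params.auto_threshold:
        t_low, t_high = compute_thresholds(arr)
    else:
        t_low, t_high = params.t_low, params.t_high

    labels = np.full(arr.shape, BACKGROUND, dtype=np.int8)
    labels[arr >= t_low] = BIOFILM
    labels[arr >= t_high] = SURFACE
    return labels


def _column_runs(column_is_surface: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a 1D boolean column as (start, stop) inclusive."""
    idx = np.flatnonzero(column_is_surface)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, stops)]


def detect_surface(labels: LabelVolume, params: SegmentationParams) -> SurfaceModel:
    """Locate the plastic surface top per lateral column.

    Per A-scan, maximal consecutive runs of SURFACE voxels of length >=
    ``min_surface_run`` qualify; the longest wins and ties go to the deeper
    run, which suppresses thin bright speckle above the plate.  The surface
    row is the shallowest voxel of the selected run.
    """
    lab = labels.labels
    ny, nz, nx = lab.shape
    top = np.full((ny, nx), NOT_FOUND, dtype=int)
    bottom = np.full((ny, nx), NOT_FOUND, dtype=int)
    is_surface = lab == SURFACE
    for y in range(ny):
        for x in range(nx):
            runs = [r for r in _column_runs(is_surface[y, :, x])
                    if r[1] - r[0] + 1 >= params.min_surface_run]
            if not runs:
                continue
            best_len = max(r[1] - r[0] + 1 for r in runs)
            # tie -> deeper run (largest start index among the longest runs)
            best = max((r for r in runs if r[1] - r[0] + 1 == best_len), key=lambda r: r[0])
            top[y, x], bottom[y, x] = best
    return SurfaceModel(surface_row=top, surface_bottom=bottom)


def remove_subsurface(labels: LabelVolume, surface: SurfaceModel) -> LabelVolume:
    """Relabel biofilm voxels below the plastic surface as background.

    "Below" is relative to the bottom of the selected surface run.  Columns
    with no detected surface lose ALL biofilm voxels (they contribute zero
    thickness downstream).  SURFACE voxels are never touched; the result is
    a new partition.
    """
    lab = labels.labels
    ny, nz, nx = lab.shape
    if surface.surface_row.shape != (ny, nx):
        raise ValueError(
            f"surface grid shape {surface.surface_row.shape} does not match "
            f"label volume lateral shape {(ny, nx)}"
        )
    out = lab.copy()
    rows = np.arange(nz)[None, :, None]  # (1, nz, 1) broadcast over (y, z, x)
    bottom = surface.surface_bottom[:, None, :]
    found = surface.found[:, None, :]
    below = found & (rows > bottom)
    kill = (out == BIOFILM) & (below | ~found)
    out[kill] = BACKGROUND
    return LabelVolume(labels=out)
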