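"""Synthetic OCT phantoms with known, voxel-quantised biofilm thickness.

The study's raw volume scans were never deposited, so validation runs on
phantoms that emulate the imaged scene: a bright (possibly tilted) plastic
surface band, a medium-intensity biofilm layer of known thickness adhering
to the probe-side of the surface, dark background, multiplicative gamma
speckle, and medium-intensity reflection artifacts below the surface — the
very pixels the sub-surface filter exists to remove.  Ground truth is stored
AFTER voxel quantisation so exact recovery assertions are well-posed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .geometry import DEFAULT_GEOMETRY, VoxelGeometry
from .oct_io import OCTVolume


@dataclass
class PhantomSpec:
    """Everything needed to build one phantom volume, deterministically.

    Thickness parameters (μm) by field kind:
      flat  — ``{"T": μm}`` constant slab;
      ramp  — ``{"T_min": μm, "T_max": μm}`` linear in lateral x;
      rough — ``{"T_mean": μm, "amplitude": μm, "correlation_length": columns}``
              moving-average-smoothed Gaussian field, clipped at 0.

    ``speckle_shape`` is the gamma shape of mean-1 multiplicative speckle
    (``math.inf`` = noiseless).  ``artifact_rate`` is the expected fraction
    of lateral columns seeded with a medium-intensity reflection blob below
    the surface band.
    """

    shape: tuple[int, int, int] = (16, 256, 128)  # (n_bscans, n_axial, n_lateral)
    geometry: VoxelGeometry = field(default_factory=lambda: DEFAULT_GEOMETRY)
    surface_depth_row: int = 160
    surface_tilt: float = 0.0  # axial rows per lateral column
    surface_band_rows: int = 12
    thickness_field_kind: str = "flat"
    thickness_params: dict = field(default_factory=lambda: {"T": 43.5})
    class_intensities: tuple[float, float, float] = (0.05, 0.45, 0.90)
    speckle_shape: float = math.inf
    artifact_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be three positive extents, got {self.shape}")
        bg, bio, surf = self.class_intensities
        if not (0 <= bg < bio < surf <= 1):
            raise ValueError(
                f"class intensities must satisfy 0 <= background < biofilm <= surface <= 1, "
                f"got {self.class_intensities}"
            )
        if self.surface_band_rows < 1:
            raise ValueError("surface_band_rows must be >= 1")
        if not (0.0 <= self.artifact_rate <= 1.0):
            raise ValueError("artifact_rate must be in [0, 1]")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive (math.inf = noiseless)")
        if self.thickness_field_kind not in ("flat", "ramp", "rough"):
            raise ValueError(f"unknown thickness_field_kind {self.thickness_field_kind!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        if "geometry" in cfg:
            cfg["geometry"] = VoxelGeometry(**cfg["geometry"])
        if "shape" in cfg:
            cfg["shape"] = tuple(cfg["shape"])
        if "class_intensities" in cfg:
            cfg["class_intensities"] = tuple(cfg["class_intensities"])
        if cfg.get("speckle_shape") in ("inf", None) and "speckle_shape" in cfg:
            cfg["speckle_shape"] = math.inf
        return cls(**cfg)


@dataclass
class GroundTruth:
    """Planted quantities of a phantom: thickness (μm, voxel-quantised) and
    surface top row, both on the lateral (y, x) grid."""

    thickness_map_um: np.ndarray
    surface_row: np.ndarray
    thickness_voxels: np.ndarray


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def make_thickness_field(spec: PhantomSpec) -> np.ndarray:
    """Planted thickness field in μm, quantised to whole axial voxels.

    Quantisation is round-half-up on T / axial_res; the returned grid is
    therefore an exact integer multiple of the axial voxel size everywhere.
    """
    ny, nz, nx = spec.shape
    p = spec.thickness_params
    kind = spec.thickness_field_kind
    if kind == "flat":
        T = float(p["T"])
        if T < 0:
            raise ValueError("flat thickness T must be >= 0")
        field_um = np.full((ny, nx), T)
    elif kind == "ramp":
        t0, t1 = float(p["T_min"]), float(p["T_max"])
        if t0 < 0 or t1 < 0:
            raise ValueError("ramp thickness bounds must be >= 0")
        ramp = np.linspace(t0, t1, nx)
        field_um = np.tile(ramp, (ny, 1))
    else:  # rough
        t_mean = float(p["T_mean"])
        amp = float(p["amplitude"])
        corr = int(p.get("correlation_length", 8))
        if t_mean < 0 or amp < 0 or corr < 1:
            raise ValueError("rough field needs T_mean, amplitude >= 0 and correlation_length >= 1")
        rng = np.random.default_rng(spec.seed)
        noise = rng.standard_normal((ny, nx + corr - 1))
        kernel = np.ones(corr) / corr
        smooth = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), 1, noise)
        # moving average shrinks the variance by ~corr; rescale to unit sd
        smooth = smooth / max(smooth.std(), 1e-12)
        field_um = np.clip(t_mean + amp * smooth, 0.0, None)

    voxels = _round_half_up(field_um / spec.geometry.axial_res)
    return voxels * spec.geometry.axial_res


def simulate_volume(spec: PhantomSpec) -> tuple[OCTVolume, GroundTruth]:
    """Build one phantom volume plus its ground truth.

    Scene assembly per lateral column: background everywhere; a bright
    surface band of ``surface_band_rows`` starting at the (tilt-rounded)
    surface top row; biofilm voxels stacked immediately above the surface
    top per the quantised thickness field; with probability
    ``artifact_rate``, a biofilm-intensity reflection blob strictly below
    the surface band.  Mean class intensities are then multiplied by gamma
    speckle (mean 1, shape ``speckle_shape``) when finite and clipped to
    [0, 1].  Same seed, same spec — bit-identical output.
    """
    ny, nz, nx = spec.shape
    geom = spec.geometry
    rng = np.random.default_rng(spec.seed)

    field_um = make_thickness_field(spec)
    voxels = _round_half_up(field_um / geom.axial_res)

    x = np.arange(nx)
    surface_top_1d = _round_half_up(spec.surface_depth_row + spec.surface_tilt * x)
    surface_top = np.tile(surface_top_1d, (ny, 1))

    max_thick = int(voxels.max())
    min_top = int(surface_top.min())
    max_bottom = int(surface_top.max()) + spec.surface_band_rows - 1
    if min_top - max_thick < 0 or max_bottom >= nz:
        needed = max_thick + (max_bottom - min_top + 1)
        raise ValueError(
            f"scene overflows the axial extent (surface rows {min_top}..{max_bottom}, "
            f"thickest biofilm {max_thick} voxels, n_axial {nz}); "
            f"need n_axial >= {needed} with a suitable surface_depth_row"
        )

    bg_i, bio_i, surf_i = spec.class_intensities
    intensities = np.full((ny, nz, nx), bg_i)

    rows = np.arange(nz)[None, :, None]
    top = surface_top[:, None, :]
    thick = voxels[:, None, :]
    band = (rows >= top) & (rows < top + spec.surface_band_rows)
    film = (rows >= top - thick) & (rows < top)
    intensities[film] = bio_i
    intensities[band] = surf_i

    # sub-surface reflection artifacts: medium-intensity blobs the cleanup
    # stage must delete; drawn AFTER the scene so the same seed plants the
    # same biofilm whatever the artifact rate
    if spec.artifact_rate > 0:
        band_bottom = surface_top + spec.surface_band_rows - 1
        for yy in range(ny):
            hit = rng.random(nx) < spec.artifact_rate
            for xx in np.flatnonzero(hit):
                lo = band_bottom[yy, xx] + 2  # keep a gap so the median filter
                if lo + 4 >= nz:              # cannot bridge blob and band
                    continue
                height = int(rng.integers(4, 9))
                start = int(rng.integers(lo, max(lo + 1, nz - height)))
                stop = min(start + height, nz)
                half_w = int(rng.integers(1, 5))
                x0, x1 = max(0, xx - half_w), min(nx, xx + half_w + 1)
                intensities[yy, start:stop, x0:x1] = bio_i

    if math.isfinite(spec.speckle_shape):
        k = spec.speckle_shape
        speckle = rng.gamma(shape=k, scale=1.0 / k, size=intensities.shape)
        intensities = intensities * speckle
    intensities = np.clip(intensities, 0.0, 1.0)

    volume = OCTVolume(intensities=intensities, geometry=geom,
                       source_id=f"phantom(seed={spec.seed},kind={spec.thickness_field_kind})")
    truth = GroundTruth(thickness_map_um=field_um, surface_row=surface_top,
                        thickness_voxels=voxels)
    return volume, truth
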