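"""Reading and writing OCT volumes and derived thickness maps.

Volumes are multi-page grayscale TIFF stacks (one B-scan per page) or raw
``.npy``/``.npz`` arrays.  Pages are stacked on axis 0, so the volume is
indexed (B-scan y, axial row z, lateral column x).  Integer pixel data are
cast to float without rescaling; normalisation is the segmentation stage's
concern, not the reader's.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import tifffile

from .geometry import VoxelGeometry

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for typing only
    from .thickness import ThicknessMap


@dataclass
class OCTVolume:
    """A 3D OCT intensity volume with explicit voxel geometry.

    ``intensities`` is indexed (bscan y, axial row z, lateral column x);
    row 0 of each B-scan page is nearest the probe.  Values are finite and
    non-negative on their native scale.
    """

    intensities: np.ndarray
    geometry: VoxelGeometry
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 3 or arr.size == 0:
            raise ValueError(f"intensities must be a non-empty 3D array, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if arr.min() < 0:
            raise ValueError("intensities must be non-negative")
        self.intensities = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def n_bscans(self) -> int:
        return self.intensities.shape[0]


def read_volume(path: str | Path, geometry: VoxelGeometry) -> OCTVolume:
    """Read an OCT volume from a multi-page TIFF or a raw array file.

    TIFF pages must all be 2D (grayscale) and share one shape; RGB or
    multi-channel pages are rejected, naming the offending page.  ``.npy``
    and ``.npz`` files (key ``intensities``, fallback: sole array) are
    accepted as raw 3D stacks.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")

    suffix = path.suffix.lower()
    if suffix in (".npy", ".npz"):
        if suffix == ".npy":
            arr = np.load(path)
        else:
            with np.load(path) as npz:
                if "intensities" in npz:
                    arr = npz["intensities"]
                elif len(npz.files) == 1:
                    arr = npz[npz.files[0]]
                else:
                    raise ValueError(
                        f"{path}: ambiguous npz, expected key 'intensities' among {npz.files}"
                    )
        if arr.ndim == 2:
            arr = arr[np.newaxis]
        return OCTVolume(np.asarray(arr, dtype=float), geometry, source_id=str(path))

    pages = _read_tiff_pages(path)
    return OCTVolume(np.asarray(pages, dtype=float), geometry, source_id=str(path))


def _read_tiff_pages(path: Path) -> np.ndarray:
    """Page-by-page TIFF read with per-page shape/channel validation."""
    with tifffile.TiffFile(str(path)) as tif:
        arrays = []
        first_shape: tuple[int, ...] | None = None
        for i, page in enumerate(tif.pages):
            a = page.asarray()
            if a.ndim != 2:
                raise ValueError(
                    f"{path}: page {i} is not grayscale (shape {a.shape}); "
                    "RGB/multi-channel volumes are not supported"
                )
            if first_shape is None:
                first_shape = a.shape
            elif a.shape != first_shape:
                raise ValueError(
                    f"{path}: page {i} has shape {a.shape}, inconsistent with "
                    f"page 0 shape {first_shape}"
                )
            arrays.append(a)
        if not arrays:
            raise ValueError(f"{path}: TIFF contains no pages")
    return np.stack(arrays, axis=0)


def write_volume(volume: OCTVolume, path: str | Path) -> None:
    """Write a volume as a float32 multi-page TIFF (one B-scan per page)."""
    path = Path(path)
    tifffile.imwrite(str(path), volume.intensities.astype(np.float32))


def write_thickness_map(tmap: "ThicknessMap", path: str | Path) -> None:
    """Write a thickness map as TSV plus a JSON summary sidecar.

    The TSV has columns (y_index, x_index, thickness_um), thickness printed
    to 6 decimals; the sidecar ``<path>.json`` records mean, sample sd and
    the fraction of columns with a detected surface.
    """
    from .thickness import mean_thickness  # local import avoids a cycle

    values = np.asarray(tmap.values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot write an empty thickness map")
    if not np.all(np.isfinite(values)):
        raise ValueError("thickness map contains non-finite values")

    path = Path(path)
    ny, nx = values.shape
    with open(path, "w") as fh:
        fh.write("y_index\tx_index\tthickness_um\n")
        for y in range(ny):
            for x in range(nx):
                fh.write(f"{y}\t{x}\t{values[y, x]:.6f}\n")

    flat = values.ravel()
    summary = {
        "mean_um": float(np.mean(flat)),
        "sd_um": float(np.std(flat, ddof=1)) if flat.size > 1 else 0.0,
        "valid_fraction": float(np.mean(np.asarray(tmap.surface_found, dtype=bool))),
        "n_points": int(flat.size),
        "axial_res_um": tmap.geometry.axial_res,
        "lateral_res_x_um": tmap.geometry.lateral_res_x,
        "lateral_res_y_um": tmap.geometry.lateral_res_y,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(summary, fh, indent=1)
        fh.write("\n")


def read_thickness_map(path: str | Path, geometry: VoxelGeometry) -> "ThicknessMap":
    """Read back a thickness-map TSV written by :func:`write_thickness_map`."""
    from .thickness import ThicknessMap

    path = Path(path)
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    data = np.atleast_2d(data)
    ys = data[:, 0].astype(int)
    xs = data[:, 1].astype(int)
    values = np.zeros((ys.max() + 1, xs.max() + 1))
    values[ys, xs] = data[:, 2]
    return ThicknessMap(values=values, geometry=geometry, surface_found=values > 0)
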