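"""Readers and writers for images, label grids and seed maps.

2D grayscale images come and go as PNG/TIFF through imageio; 3D volumes as
NIfTI-1 through nibabel.  Intensities are scaled to [0, 1] by the
container's bit-depth maximum on read (an 8-bit value of 26 becomes
26/255).  Label images use 0 for "unlabelled" in seed files and
0 = background / 1 = foreground in segmentation outputs; round-trips are
bit-exact.  Seed maps may also travel as CSV tables of (coords..., label)
rows.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Optional, Tuple

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .seeding import SeedMap

__all__ = [
    "read_image",
    "write_labels",
    "read_labels",
    "read_seeds",
    "write_seeds_csv",
    "read_seeds_csv",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_image(path) -> Tuple[np.ndarray, dict]:
    """Read an image or volume and scale intensities to [0, 1].

    Returns (features, meta) where meta records the original dtype, the
    scale divisor and (for NIfTI) the affine, so outputs can be written
    back into the same geometry.  RGB images are collapsed to luminance
    with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    meta: dict = {"path": str(path)}
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        meta["affine"] = img.affine
        meta["nifti"] = True
    else:
        data = iio.imread(path)
        meta["nifti"] = False
    if data.ndim == 3 and not meta["nifti"] and data.shape[-1] in (3, 4):
        warnings.warn("RGB(A) input converted to luminance", stacklevel=2)
        rgb = data[..., :3].astype(np.float64)
        data = 0.2126 * rgb[..., 0] + 0.7152 * rgb[..., 1] + 0.0722 * rgb[..., 2]
        # luminance of a uint image still lives on the original dtype scale
        meta["rgb"] = True
    meta["dtype"] = str(np.asarray(data).dtype)
    arr = np.asarray(data, dtype=np.float64)
    if np.issubdtype(np.asarray(data).dtype, np.integer):
        divisor = float(np.iinfo(np.asarray(data).dtype).max)
    elif meta.get("rgb"):
        divisor = 255.0
    else:
        top = float(arr.max()) if arr.size else 1.0
        divisor = top if top > 1.0 else 1.0
    meta["scale"] = divisor
    features = np.clip(arr / divisor, 0.0, 1.0)
    if meta["nifti"]:
        # nibabel volumes arrive (x, y, z); present slices along axis 0
        features = np.transpose(features, (2, 0, 1))
    return features, meta


def write_labels(
    grid: np.ndarray, path, affine: Optional[np.ndarray] = None
) -> None:
    """Write an integer label grid as PNG/TIFF (2D) or NIfTI (3D)."""
    path = Path(path)
    grid = np.asarray(grid)
    if grid.min() < 0:
        raise ValueError("label values must be non-negative")
    if _is_nifti(path):
        vol = np.transpose(grid.astype(np.int16), (1, 2, 0))
        img = nib.Nifti1Image(vol, affine if affine is not None else np.eye(4))
        nib.save(img, str(path))
        return
    if grid.ndim != 2:
        raise ValueError("PNG/TIFF label output requires a 2D grid")
    if grid.max() > np.iinfo(np.uint16).max:
        raise ValueError("label values exceed 16-bit container depth")
    dtype = np.uint8 if grid.max() <= np.iinfo(np.uint8).max else np.uint16
    iio.imwrite(path, grid.astype(dtype))


def read_labels(path) -> np.ndarray:
    """Read an integer label grid written by :func:`write_labels`."""
    path = Path(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        return np.transpose(np.asanyarray(img.dataobj).astype(np.int32), (2, 0, 1))
    return np.asarray(iio.imread(path)).astype(np.int32)


def read_seeds(path) -> SeedMap:
    """Read a seed map from a label image (0 = unlabelled)."""
    grid = read_labels(path)
    return SeedMap.from_label_grid(grid)


def write_seeds_csv(seeds: SeedMap, path) -> None:
    d = seeds.coords.shape[1] if len(seeds) else 2
    header = [f"coord{i}" for i in range(d)] + ["label"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for coord, label in zip(seeds.coords, seeds.labels):
            writer.writerow([*map(int, coord), int(label)])


def read_seeds_csv(path) -> SeedMap:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) <= 1:
        return SeedMap(np.empty((0, 2), dtype=np.int64), np.empty(0, dtype=np.int64))
    body = np.array([[int(v) for v in row] for row in rows[1:]], dtype=np.int64)
    return SeedMap(body[:, :-1], body[:, -1])
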