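"""Seed maps and algorithmic seed generation.

GrowCut needs initial labelled cells ("seeds") with full strength 1.  To
remove the subjectivity of hand-painted scribbles, seeds can be generated
from a ground-truth mask: for each of the two regions (background and
foreground) the tallest contiguous vertical run of that region's pixels in
any single column is selected and trimmed to a fraction of its height
(75% by default), centred within the run.

Conventions: ground-truth masks are binary (0 = background, 1 = foreground);
seed labels are ``1`` for background and ``2`` for foreground
(:data:`BACKGROUND_LABEL`, :data:`FOREGROUND_LABEL`).  Label value 0 is
reserved for "unlabelled" in seed images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

BACKGROUND_LABEL = 1
FOREGROUND_LABEL = 2

__all__ = [
    "SeedMap",
    "generate_vertical_seeds",
    "generate_vertical_seeds_volume",
    "BACKGROUND_LABEL",
    "FOREGROUND_LABEL",
]


@dataclass
class SeedMap:
    """Sparse (coordinate, label) assignments; seeds carry strength 1.

    ``coords`` is an (n, d) integer array, ``labels`` an (n,) integer array
    with values >= 1.  Coordinates must be unique.
    """

    coords: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=np.int64))
        self.labels = np.asarray(self.labels, dtype=np.int64).ravel()
        if self.coords.shape[0] != self.labels.shape[0]:
            raise ValueError("coords and labels must have equal length")
        if self.labels.size and self.labels.min() < 1:
            raise ValueError("seed labels must be >= 1 (0 means unlabelled)")
        if self.coords.shape[0]:
            uniq = np.unique(self.coords, axis=0)
            if uniq.shape[0] != self.coords.shape[0]:
                raise ValueError("seed coordinates must be unique")

    def __len__(self) -> int:
        return int(self.labels.size)

    @property
    def d(self) -> int:
        return int(self.coords.shape[1]) if len(self) else 0

    @classmethod
    def from_label_grid(cls, grid: np.ndarray) -> "SeedMap":
        """Build from a label image where 0 marks unlabelled cells."""
        grid = np.asarray(grid)
        coords = np.argwhere(grid > 0)
        labels = grid[tuple(coords.T)] if coords.size else np.empty(0, int)
        if coords.shape[0] == 0:
            warnings.warn("seed grid contains no labelled cells", stacklevel=2)
            coords = np.empty((0, grid.ndim), dtype=np.int64)
        return cls(coords, labels)

    def to_label_grid(self, shape: Sequence[int]) -> np.ndarray:
        grid = np.zeros(tuple(shape), dtype=np.int32)
        if len(self):
            if self.coords.shape[1] != len(shape):
                raise ValueError("seed dimensionality does not match shape")
            if (self.coords < 0).any() or (self.coords >= np.asarray(shape)).any():
                raise ValueError("seed coordinate outside grid")
            grid[tuple(self.coords.T)] = self.labels
        return grid

    def merged_with(self, other: "SeedMap") -> "SeedMap":
        if len(self) == 0:
            return other
        if len(other) == 0:
            return self
        return SeedMap(
            np.vstack([self.coords, other.coords]),
            np.concatenate([self.labels, other.labels]),
        )


def _tallest_run(mask: np.ndarray) -> Tuple[int, int, int]:
    """Tallest contiguous vertical run of True pixels.

    Returns (column, start_row, height); ties broken by leftmost column,
    then topmost run.  Raises if the mask is empty.
    """
    if not mask.any():
        raise ValueError("region has no pixels")
    best = (0, 0, 0)  # (height, col, start) with sign flip for comparison
    n_rows, n_cols = mask.shape
    for col in range(n_cols):
        column = mask[:, col]
        row = 0
        while row < n_rows:
            if column[row]:
                start = row
                while row < n_rows and column[row]:
                    row += 1
                height = row - start
                if height > best[0]:
                    best = (height, col, start)
            else:
                row += 1
    height, col, start = best
    return col, start, height


def _trim_centered(start: int, height: int, fraction: float) -> Tuple[int, int]:
    keep = max(1, int(np.floor(fraction * height)))
    slack = height - keep
    top = start + slack // 2
    return top, keep


def generate_vertical_seeds(
    gt: np.ndarray, fraction: float = 0.75
) -> SeedMap:
    """Generate one vertical line seed per region from a binary ground truth.

    For background (gt == 0) and foreground (gt == 1) alike, the tallest
    contiguous same-column run of the region is found, trimmed to
    ``max(1, floor(fraction * height))`` pixels centred within the run, and
    emitted with the region's seed label (1 = background, 2 = foreground).
    """
    gt = np.asarray(gt)
    if gt.ndim != 2:
        raise ValueError("ground truth must be 2D; use the volume variant for 3D")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    coords, labels = [], []
    for region_value, label, name in (
        (0, BACKGROUND_LABEL, "background"),
        (1, FOREGROUND_LABEL, "foreground"),
    ):
        mask = gt == region_value
        if not mask.any():
            raise ValueError(f"{name} region absent from ground truth")
        col, start, height = _tallest_run(mask)
        top, keep = _trim_centered(start, height, fraction)
        for row in range(top, top + keep):
            coords.append((row, col))
            labels.append(label)
    return SeedMap(np.array(coords), np.array(labels))


def generate_vertical_seeds_volume(
    gt: np.ndarray, fraction: float = 0.75
) -> SeedMap:
    """Per-slice vertical seeds for a 3D ground truth (axis 0 = slice).

    Slices missing one of the two regions contribute no seeds for it (a
    warning is emitted); the engine's stitch mode then leaves fully
    unseeded slices unlabelled.
    """
    gt = np.asarray(gt)
    if gt.ndim != 3:
        raise ValueError("expected a 3D ground truth volume")
    coords, labels = [], []
    for z in range(gt.shape[0]):
        sl = gt[z]
        for region_value, label, name in (
            (0, BACKGROUND_LABEL, "background"),
            (1, FOREGROUND_LABEL, "foreground"),
        ):
            mask = sl == region_value
            if not mask.any():
                warnings.warn(
                    f"slice {z}: {name} region absent, no seed generated",
                    stacklevel=2,
                )
                continue
            col, start, height = _tallest_run(mask)
            top, keep = _trim_centered(start, height, fraction)
            for row in range(top, top + keep):
                coords.append((z, row, col))
                labels.append(label)
    if not coords:
        return SeedMap(np.empty((0, 3), dtype=np.int64), np.empty(0, dtype=np.int64))
    return SeedMap(np.array(coords), np.array(labels))
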