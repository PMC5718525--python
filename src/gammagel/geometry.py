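"""Dose-grid container and geometry operations in the Leksell frame.

All public coordinates are millimetres in the stereotactic (Leksell) X/Y/Z
system.  Grids use a voxel-centre convention with fixed axis order (X, Y, Z):
``data[ix, iy, iz]`` sits at ``origin + index * spacing``.  Missing values
("no data") are represented as NaN and propagate through every operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "GridGeometry",
    "DoseGrid",
    "Box",
    "resample",
    "extract_subvolume",
    "extract_plane",
]

_AXES = ("X", "Y", "Z")


@dataclass(frozen=True)
class GridGeometry:
    """Regular 3D lattice: origin (mm, centre of voxel [0,0,0]), spacing (mm),
    shape (voxel counts), axis order fixed as (X, Y, Z)."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.shape) != 3:
            raise ValueError("origin, spacing and shape must all have length 3")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be >= 1 on all axes, got {self.shape}")

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates (mm) along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    @property
    def extent(self) -> tuple[tuple[float, float], ...]:
        """(min, max) voxel-centre coordinate per axis, inclusive."""
        return tuple(
            (self.origin[i], self.origin[i] + self.spacing[i] * (self.shape[i] - 1))
            for i in range(3)
        )

    def to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map mm coordinates (…, 3) to fractional voxel indices (…, 3)."""
        pts = np.asarray(points_mm, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def meshgrid_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(*(self.axis_coords(i) for i in range(3)), indexing="ij")

    def to_dict(self) -> dict:
        return {
            "origin": list(self.origin),
            "spacing": list(self.spacing),
            "shape": list(self.shape),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridGeometry":
        return cls(tuple(d["origin"]), tuple(d["spacing"]), tuple(d["shape"]))


@dataclass
class DoseGrid:
    """3D scalar dose array (Gy) with its geometry.  NaN marks no-data voxels.

    Planes are represented as grids with a singleton axis, so every comparison
    operation works unchanged in 2D.
    """

    data: np.ndarray
    geometry: GridGeometry
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.geometry.shape:
            raise ValueError(
                f"data shape {self.data.shape} != geometry shape {self.geometry.shape}"
            )

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.data)

    def max(self) -> float:
        return float(np.nanmax(self.data))

    def copy(self) -> "DoseGrid":
        return DoseGrid(self.data.copy(), self.geometry, dict(self.meta))


@dataclass(frozen=True)
class Box:
    """Axis-aligned box, inclusive mm bounds per axis."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lo", tuple(float(v) for v in self.lo))
        object.__setattr__(self, "hi", tuple(float(v) for v in self.hi))
        for i in range(3):
            if self.lo[i] > self.hi[i]:
                raise ValueError(f"box min > max on axis {_AXES[i]}")

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.asarray(points_mm, dtype=float)
        return np.all((pts >= self.lo) & (pts <= self.hi), axis=-1)


def sample_at(grid: DoseGrid, points_mm: np.ndarray) -> np.ndarray:
    """Trilinear sample of a grid at arbitrary mm points (no extrapolation).

    Points outside the voxel-centre support, or whose interpolation stencil
    touches a no-data voxel, return NaN.
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    idx = grid.geometry.to_index(pts)
    n = np.asarray(grid.geometry.shape, dtype=float)
    inside = np.all((idx >= 0.0) & (idx <= n - 1.0), axis=-1)
    out = ndimage.map_coordinates(
        grid.data, idx.T, order=1, mode="constant", cval=np.nan, prefilter=False
    )
    out[~inside] = np.nan
    return out.reshape(np.asarray(points_mm, dtype=float).shape[:-1])


def resample(grid: DoseGrid, target: GridGeometry) -> DoseGrid:
    """Trilinear resampling onto the target lattice.

    Target voxels outside the source voxel-centre support are marked no-data
    (NaN); there is no extrapolation.  Trilinear interpolation is convex, so
    output values never leave the [min, max] range of the source.
    """
    for i in range(3):
        (slo, shi), (tlo, thi) = grid.geometry.extent[i], target.extent[i]
        if thi < slo or tlo > shi:
            raise ValueError(
                f"target extent disjoint from source on axis {_AXES[i]}: "
                f"source [{slo}, {shi}] mm vs target [{tlo}, {thi}] mm"
            )
    xs, ys, zs = (target.axis_coords(i) for i in range(3))
    pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    data = sample_at(grid, pts.reshape(-1, 3)).reshape(target.shape)
    return DoseGrid(data, target, dict(grid.meta))


def extract_subvolume(grid: DoseGrid, box: Box) -> DoseGrid:
    """Voxels whose centres fall inside the inclusive mm box."""
    slices = []
    new_origin = []
    for i in range(3):
        coords = grid.geometry.axis_coords(i)
        keep = np.nonzero((coords >= box.lo[i]) & (coords <= box.hi[i]))[0]
        if keep.size == 0:
            raise ValueError(
                f"box [{box.lo[i]}, {box.hi[i]}] mm contains no voxel centres "
                f"on axis {_AXES[i]}"
            )
        slices.append(slice(keep[0], keep[-1] + 1))
        new_origin.append(coords[keep[0]])
    geom = GridGeometry(
        tuple(new_origin),
        grid.geometry.spacing,
        tuple(s.stop - s.start for s in slices),
    )
    return DoseGrid(grid.data[tuple(slices)].copy(), geom, dict(grid.meta))


def extract_plane(
    grid: DoseGrid, axis: int | str, coordinate: float, atol: float = 1e-6
) -> DoseGrid:
    """Extract the plane at a fixed mm coordinate along one axis.

    If the coordinate coincides with a slice centre (within ``atol`` mm) the
    slice is returned bit-exactly; otherwise the two bracketing slices are
    linearly interpolated.  The result keeps a singleton axis so downstream
    operations treat it as a (degenerate) 3D grid.
    """
    if isinstance(axis, str):
        axis = _AXES.index(axis.upper())
    coords = grid.geometry.axis_coords(axis)
    if coordinate < coords[0] - atol or coordinate > coords[-1] + atol:
        raise ValueError(
            f"coordinate {coordinate} mm outside grid extent "
            f"[{coords[0]}, {coords[-1]}] mm on axis {_AXES[axis]}"
        )
    j = int(np.argmin(np.abs(coords - coordinate)))
    if abs(coords[j] - coordinate) <= atol:
        plane = np.take(grid.data, j, axis=axis).copy()
        coord_used = coords[j]
    else:
        j0 = int(np.searchsorted(coords, coordinate) - 1)
        j0 = min(max(j0, 0), len(coords) - 2)
        t = (coordinate - coords[j0]) / (coords[j0 + 1] - coords[j0])
        a = np.take(grid.data, j0, axis=axis)
        b = np.take(grid.data, j0 + 1, axis=axis)
        plane = (1.0 - t) * a + t * b
        coord_used = coordinate
    origin = list(grid.geometry.origin)
    spacing = list(grid.geometry.spacing)
    shape = list(grid.geometry.shape)
    origin[axis] = float(coord_used)
    shape[axis] = 1
    geom = GridGeometry(tuple(origin), tuple(spacing), tuple(shape))
    return DoseGrid(np.expand_dims(plane, axis=axis), geom, dict(grid.meta))
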