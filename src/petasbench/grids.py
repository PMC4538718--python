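"""Regular 3-D grids with millimetre world coordinates.

Arrays are indexed ``(i, j, k)`` along ``(x, y, z)``; axial slices are
fixed-``k`` planes.  Voxel ``(i, j, k)`` is centred at
``origin + index * spacing`` and covers a box of one spacing around its
centre.  All geometry (templates, simulated PET images, masks) shares this
convention, so resampling between grids is a pure world-coordinate mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec", "cover_grid", "overlap_matrix", "resample_mean"]


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned regular grid: voxel counts, spacing (mm) and origin (mm).

    The origin is the world position of the centre of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("GridSpec fields must have exactly three entries")
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if any(n < 1 for n in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacings must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    # -- geometry -----------------------------------------------------------

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size of the grid (mm) including the half-voxel borders."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def centre(self) -> tuple[float, float, float]:
        """World coordinates of the grid's geometric centre."""
        return tuple(
            o + (n - 1) / 2.0 * s for o, n, s in zip(self.origin, self.shape, self.spacing)
        )

    def axis_centres(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (sparse) world-coordinate arrays for all voxel centres."""
        return np.meshgrid(
            self.axis_centres(0), self.axis_centres(1), self.axis_centres(2),
            indexing="ij", sparse=True,
        )

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        index = np.asarray(index, dtype=float)
        return self.origin + index * np.asarray(self.spacing)

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world positions (mm)."""
        world = np.asarray(world, dtype=float)
        return (world - np.asarray(self.origin)) / np.asarray(self.spacing)

    def world_to_voxel(self, world: np.ndarray) -> np.ndarray:
        """Nearest voxel indices of world positions (mm)."""
        return np.round(self.world_to_index(world)).astype(int)

    def contains_index(self, index: np.ndarray) -> np.ndarray:
        index = np.asarray(index)
        return np.all((index >= 0) & (index < np.asarray(self.shape)), axis=-1)

    # -- interop ------------------------------------------------------------

    @property
    def affine(self) -> np.ndarray:
        """NIfTI-style 4x4 voxel-to-world affine (axis aligned)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    @classmethod
    def from_affine(cls, shape: tuple[int, int, int], affine: np.ndarray) -> "GridSpec":
        affine = np.asarray(affine, dtype=float)
        rot = affine[:3, :3]
        if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
            raise ValueError("only axis-aligned affines are supported")
        spacing = np.diag(rot)
        if np.any(spacing <= 0):
            raise ValueError("negative or zero spacings in affine (flipped axes unsupported)")
        return cls(tuple(shape), tuple(spacing), tuple(affine[:3, 3]))

    def same_geometry(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


def cover_grid(source: GridSpec, spacing: tuple[float, float, float]) -> GridSpec:
    """Grid with the given spacing covering ``source``'s extent, co-centred.

    Used to derive the coarse PET grid from a fine template grid.
    """
    spacing = tuple(float(s) for s in spacing)
    shape = tuple(max(1, int(round(e / s))) for e, s in zip(source.extent, spacing))
    origin = tuple(
        c - (n - 1) / 2.0 * s for c, n, s in zip(source.centre, shape, spacing)
    )
    return GridSpec(shape, spacing, origin)


def overlap_matrix(source: GridSpec, target: GridSpec, axis: int) -> np.ndarray:
    """Per-axis box-overlap lengths between source and target voxel intervals.

    Entry ``(i, j)`` is the length (mm) of the intersection of source voxel
    ``i``'s interval with target voxel ``j``'s interval along ``axis``.
    Because both grids are axis aligned, 3-D voxel overlap volumes factorise
    into the product of these per-axis lengths.
    """
    sc = source.axis_centres(axis)
    tc = target.axis_centres(axis)
    shalf = source.spacing[axis] / 2.0
    thalf = target.spacing[axis] / 2.0
    lo = np.maximum(sc[:, None] - shalf, tc[None, :] - thalf)
    hi = np.minimum(sc[:, None] + shalf, tc[None, :] + thalf)
    return np.clip(hi - lo, 0.0, None)


def resample_mean(
    values: np.ndarray, source: GridSpec, target: GridSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Exact partial-volume resampling of a source field onto a target grid.

    Integrates the (piecewise-constant) source field over each target voxel
    via separable box overlaps and returns ``(mean, covered)`` where
    ``mean`` is the average source value over the covered part of each
    target voxel (0 where uncovered) and ``covered`` is the covered volume
    in mm^3.  A constant field resamples to exactly that constant wherever
    covered, and ``sum(mean_over_covered * covered)`` equals the source
    integral over the overlap region exactly.
    """
    if values.shape != source.shape:
        raise ValueError("values shape does not match source grid")
    wx = overlap_matrix(source, target, 0)
    wy = overlap_matrix(source, target, 1)
    wz = overlap_matrix(source, target, 2)

    def contract(field: np.ndarray) -> np.ndarray:
        out = np.tensordot(wx, field, axes=(0, 0))  # (tx, sy, sz)
        out = np.tensordot(wy, out, axes=(0, 1)).transpose(1, 0, 2)  # (tx, ty, sz)
        return np.tensordot(out, wz, axes=(2, 0))  # (tx, ty, tz)

    integral = contract(np.asarray(values, dtype=float))
    covered = contract(np.ones(source.shape))
    mean = np.divide(integral, covered, out=np.zeros_like(integral), where=covered > 0)
    return mean, covered
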