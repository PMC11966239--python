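"""Microscope-frame query grids, poses, jitter and mask subsetting.

Conventions used throughout the package:

* right-handed axes, units of Angstrom, box centered on the physical origin;
* the imaging plane carries one grid point per pixel, at pixel centers
  ``(i - n/2 + 0.5) * pixel_size``;
* the viewing (z) direction has ``n_z`` points spanning the same physical
  extent as the pixel centers span in x;
* a volume array ``V[a, b, c]`` is indexed (x, y, z) with voxel centers on
  the same pixel-center lattice.

Scalar fields consume coordinates normalized to the unit cube; the affine
map from physical to normalized coordinates lives in :mod:`cryofield.fields`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "Grid",
    "Pose",
    "JitterSpec",
    "MaskVolume",
    "build_grid",
    "pose_grid",
    "jitter_points",
    "subset_by_mask",
    "axis_coords",
]

_ORTHO_TOL = 1e-6


def axis_coords(n: int, spacing: float) -> np.ndarray:
    """Pixel/voxel center positions for one axis, centered on the origin."""
    return (np.arange(n) - n / 2 + 0.5) * spacing


@dataclass
class Grid:
    """Axis-aligned lattice of field query points in the microscope frame.

    ``points`` has shape (|G|, 3) in Angstrom; ``index_map`` holds the
    integer (a, b, c) lattice index of each point.  After mask subsetting,
    ``kept`` records the surviving flat indices into the *original*
    (unmasked) lattice so the projection operator can drop matching columns.
    """

    n_x: int
    n_y: int
    n_z: int
    spacing_x: float
    spacing_y: float
    spacing_z: float
    points: np.ndarray
    index_map: np.ndarray
    kept: np.ndarray | None = field(default=None)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def extent_x(self) -> float:
        """Physical box edge along x (n_x * spacing_x)."""
        return self.n_x * self.spacing_x


def build_grid(n_pixels: int, pixel_size: float, n_z: int) -> Grid:
    """Build the microscope-frame query grid for an ``n_pixels`` square image.

    x and y carry one point per pixel at the pixel centers.  z carries
    ``n_z`` points spanning the same physical range as the x pixel centers
    (a single plane at z = 0 when ``n_z`` is 1), so the queried slab always
    covers the full box depth regardless of the number of depth samples.
    """
    if n_pixels < 2:
        raise ValueError(f"n_pixels must be >= 2, got {n_pixels}")
    if n_z < 1:
        raise ValueError(f"n_z must be >= 1, got {n_z}")
    if pixel_size <= 0:
        raise ValueError(f"pixel_size must be > 0, got {pixel_size}")

    xs = axis_coords(n_pixels, pixel_size)
    span = xs[-1] - xs[0]
    if n_z == 1:
        zs = np.array([0.0])
        spacing_z = span if span > 0 else pixel_size
    else:
        zs = np.linspace(-span / 2, span / 2, n_z)
        spacing_z = span / (n_z - 1)

    A, B, C = np.meshgrid(
        np.arange(n_pixels), np.arange(n_pixels), np.arange(n_z), indexing="ij"
    )
    index_map = np.stack([A.ravel(), B.ravel(), C.ravel()], axis=1)
    points = np.stack(
        [xs[index_map[:, 0]], xs[index_map[:, 1]], zs[index_map[:, 2]]], axis=1
    )
    return Grid(
        n_x=n_pixels,
        n_y=n_pixels,
        n_z=n_z,
        spacing_x=pixel_size,
        spacing_y=pixel_size,
        spacing_z=spacing_z,
        points=points,
        index_map=index_map,
    )


@dataclass
class Pose:
    """Rigid pose of one particle: rotation in SO(3), in-plane shift in A."""

    R: np.ndarray
    t_x: float = 0.0
    t_y: float = 0.0

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.R.shape != (3, 3):
            raise ValueError("R must be 3x3")
        self.validate()

    def validate(self) -> None:
        err = np.abs(self.R @ self.R.T - np.eye(3)).max()
        if err > _ORTHO_TOL:
            raise ValueError(f"R is not orthogonal (max |RR^T - I| = {err:.2e})")
        if abs(np.linalg.det(self.R) - 1.0) > _ORTHO_TOL:
            raise ValueError("R must have determinant +1")

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.eye(3))


def pose_grid(grid: Grid, pose: Pose) -> np.ndarray:
    """Move the query grid into the specimen frame for one particle.

    The density stays fixed and the grid moves: each point ``p`` becomes
    ``R^{-1} p + (-t_x, -t_y, 0)``.  The grid-index -> pixel association
    (``index_map``) is pose independent and unchanged.
    """
    pose.validate()
    # R^{-1} = R^T for rotation matrices; (R^T p)^T = p^T R.
    shifted = grid.points @ pose.R
    shifted[:, 0] -= pose.t_x
    shifted[:, 1] -= pose.t_y
    return shifted


@dataclass
class JitterSpec:
    """Uniform i.i.d. jitter of width J (A) on every point coordinate."""

    J: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.J < 0:
            raise ValueError("jitter width J must be >= 0")


def jitter_points(
    points: np.ndarray,
    spec: JitterSpec,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Perturb each coordinate by an independent Uniform(-J/2, J/2) draw.

    One draw per coordinate component (|G| x 3 in total).  J = 0 returns
    the input unchanged.  Pass ``rng`` to share a generator across calls;
    otherwise ``spec.rng_seed`` seeds a fresh one (deterministic).
    """
    if spec.J == 0:
        return points
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    u = rng.uniform(-spec.J / 2, spec.J / 2, size=points.shape)
    return points + u


@dataclass
class MaskVolume:
    """Soft 3D mask on the standard voxel lattice; binarized at ``cutoff``."""

    data: np.ndarray
    spacing: float
    cutoff: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("mask data must be a 3D array")
        if np.any(self.data < 0):
            raise ValueError("mask voxels must be non-negative")

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear mask values at physical points (A); 0 outside the box."""
        n = self.data.shape[0]
        # physical -> continuous voxel index on the pixel-center lattice
        idx = points / self.spacing + n / 2 - 0.5
        return map_coordinates(
            self.data, idx.T, order=1, mode="constant", cval=0.0
        )


def subset_by_mask(grid: Grid, mask: MaskVolume) -> Grid:
    """Restrict a grid to the points whose interpolated mask value > cutoff.

    The surviving flat indices (into the unmasked lattice) are recorded in
    ``kept`` so the projection operator can drop the matching columns.
    Raises if no point survives.
    """
    values = mask.interpolate(grid.points)
    keep = values > mask.cutoff
    if not np.any(keep):
        raise ValueError(
            f"mask with cutoff {mask.cutoff} retains no grid points"
        )
    base = grid.kept if grid.kept is not None else np.arange(grid.n_points)
    return Grid(
        n_x=grid.n_x,
        n_y=grid.n_y,
        n_z=grid.n_z,
        spacing_x=grid.spacing_x,
        spacing_y=grid.spacing_y,
        spacing_z=grid.spacing_z,
        points=grid.points[keep],
        index_map=grid.index_map[keep],
        kept=base[keep],
    )
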