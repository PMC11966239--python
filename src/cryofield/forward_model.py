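"""Differentiable cryo-EM image formation.

The predicted image for one particle is built as

    points = pose(grid) -> jitter -> [bend] -> query field
    image  = reshape(M @ densities)          (sparse orthogonal projection)
    image  = IFFT( CTF(g) * FFT(image) )     (microscope optics)

The projection operator M is a fixed sparse 0/1 matrix mapping grid
index (a, b, c) to pixel (i, j) = (a, b); it is pose independent and is
built once per (grid, mask) pair.  Every step is linear or has an
explicit backward pass, so gradients flow from a pixel loss to the field
parameters (and, when bending, to the per-image deformation field).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .fields import ScalarField
from .geometry import Grid, JitterSpec, Pose, jitter_points, pose_grid

__all__ = [
    "ImagingParams",
    "Particle",
    "ProjectionMap",
    "build_projection_map",
    "project",
    "ctf_array",
    "apply_ctf",
    "render_particle",
    "render_forward",
    "render_backward",
    "electron_wavelength",
]


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstrom for a voltage in kV."""
    v = voltage_kv * 1e3
    return 12.2639 / np.sqrt(v + 0.97845e-6 * v * v)


@dataclass
class ImagingParams:
    """Microscope/CTF parameters for one particle (RELION STAR labels)."""

    defocus_u: float = 15000.0  # A
    defocus_v: float = 15000.0  # A
    astigmatism_deg: float = 0.0
    voltage_kv: float = 300.0
    cs_mm: float = 2.7
    amplitude_contrast: float = 0.1
    phase_shift_deg: float = 0.0
    pixel_size: float = 1.0  # A
    bfactor: float = 0.0  # A^2 envelope, 0 disables

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass
class Particle:
    """One observed image with its pose and imaging parameters."""

    image: np.ndarray
    pose: Pose
    ctf: ImagingParams
    identifier: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2 or self.image.shape[0] != self.image.shape[1]:
            raise ValueError("particle image must be square")
        if not np.all(np.isfinite(self.image)):
            raise ValueError("particle image contains non-finite values")


@dataclass
class ProjectionMap:
    """Sparse 0/1 matrix of shape (n^2, |G|): grid point -> image pixel."""

    M: sp.csr_matrix
    n_pixels: int

    @property
    def MT(self) -> sp.csr_matrix:
        if not hasattr(self, "_MT"):
            self._MT = self.M.T.tocsr()
        return self._MT


def build_projection_map(grid: Grid) -> ProjectionMap:
    """Build M once for a grid; masked grids simply have fewer columns."""
    n = grid.n_x
    rows = grid.index_map[:, 0] * n + grid.index_map[:, 1]
    cols = np.arange(grid.n_points)
    M = sp.csr_matrix(
        (np.ones(grid.n_points), (rows, cols)), shape=(n * n, grid.n_points)
    )
    return ProjectionMap(M=M, n_pixels=n)


def project(densities: np.ndarray, pmap: ProjectionMap) -> np.ndarray:
    """Sum the field samples over the viewing axis into an n x n image."""
    if densities.shape[0] != pmap.M.shape[1]:
        raise ValueError(
            f"density vector length {densities.shape[0]} does not match "
            f"projection map columns {pmap.M.shape[1]}"
        )
    n = pmap.n_pixels
    return (pmap.M @ densities).reshape(n, n)


def ctf_array(n: int, params: ImagingParams) -> np.ndarray:
    """CTF evaluated on the unshifted FFT frequency lattice of an n^2 image.

    chi(g) = pi*lambda*|g|^2 * df(theta) - (pi/2)*Cs*lambda^3*|g|^4 + phase
    df(theta) = (dU + dV)/2 + (dU - dV)/2 * cos(2(theta - alpha))
    CTF = sqrt(1 - A^2) sin(chi) + A cos(chi), times an optional B-factor
    envelope exp(-B|g|^2/4).

    Sign convention: CTF(0) = +A, i.e. positive low-frequency contrast, so a
    positive density produces a positive image; this equals the
    RELION/CTFFIND form up to a global sign (equivalently, the sign of the
    density).
    """
    freq = np.fft.fftfreq(n, d=params.pixel_size)
    fx = freq[:, None]
    fy = freq[None, :]
    g2 = fx * fx + fy * fy
    theta = np.arctan2(fy, fx)
    lam = electron_wavelength(params.voltage_kv)
    alpha = np.deg2rad(params.astigmatism_deg)
    df = 0.5 * (
        params.defocus_u
        + params.defocus_v
        + (params.defocus_u - params.defocus_v) * np.cos(2 * (theta - alpha))
    )
    cs = params.cs_mm * 1e7  # mm -> A
    chi = (
        np.pi * lam * g2 * df
        - 0.5 * np.pi * cs * lam**3 * g2 * g2
        + np.deg2rad(params.phase_shift_deg)
    )
    A = params.amplitude_contrast
    ctf = np.sqrt(max(1.0 - A * A, 0.0)) * np.sin(chi) + A * np.cos(chi)
    if params.bfactor:
        ctf = ctf * np.exp(-params.bfactor * g2 / 4.0)
    # The Nyquist row/column of an even-sized lattice represents +/-0.5
    # ambiguously, which breaks ctf(-g) = ctf(g) under astigmatism there.
    # A real image has a Hermitian spectrum, so the effective real->real
    # operator is multiplication by the even part: symmetrize explicitly,
    # keeping the operator linear, real and self-adjoint.
    flipped = np.roll(ctf[::-1, ::-1], (1, 1), axis=(0, 1))
    return 0.5 * (ctf + flipped)


def apply_ctf(image: np.ndarray, ctf: ImagingParams | np.ndarray) -> np.ndarray:
    """Convolve with the PSF via element-wise multiplication in Fourier space.

    Accepts either imaging parameters or a precomputed CTF array.  The CTF
    is even (ctf(-g) = ctf(g)), so the operator is linear, self-adjoint and
    returns a real image.
    """
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("apply_ctf requires a square 2D image")
    h = ctf if isinstance(ctf, np.ndarray) else ctf_array(image.shape[0], ctf)
    return np.real(np.fft.ifft2(np.fft.fft2(image) * h))


def render_forward(
    field: ScalarField,
    grid: Grid,
    pmap: ProjectionMap,
    pose: Pose,
    ctf: np.ndarray | ImagingParams | None,
    jitter: JitterSpec | None = None,
    rng: np.random.Generator | None = None,
    vf=None,
    box_extent: float | None = None,
    need_dpoints: bool = False,
):
    """Differentiable render of one particle; returns (image, cache).

    ``vf`` is an optional (3, n_F, n_F, n_F) canonical deformation field
    (see :mod:`cryofield.heterogeneity`): it is interpolated at the posed,
    jittered points and added to them before the field query (reverse
    mapping).  Gradients w.r.t. ``vf`` require ``need_dpoints`` plumbing,
    handled automatically.
    """
    from . import heterogeneity as het

    pts = pose_grid(grid, pose)
    if jitter is not None and jitter.J > 0:
        pts = jitter_points(pts, jitter, rng=rng)
    bend_cache = None
    if vf is not None:
        extent = box_extent if box_extent is not None else grid.extent_x
        pts, bend_cache = het.bend_forward(pts, vf, extent)
        # coordinate gradients are only needed to backpropagate into the
        # deformation, which requires a trainable field
        need_dpoints = need_dpoints or bool(field.params)
    dens, field_cache = field.forward(pts, need_dpoints=need_dpoints)
    image = project(dens, pmap)
    h = None
    if ctf is not None:
        h = ctf if isinstance(ctf, np.ndarray) else ctf_array(image.shape[0], ctf)
        image = apply_ctf(image, h)
    cache = (field_cache, bend_cache, h, pmap)
    return image, cache


def render_backward(field: ScalarField, cache, dimage: np.ndarray):
    """Backpropagate a pixel-space gradient through the render.

    Accumulates into ``field.grads``; returns the gradient w.r.t. the
    canonical deformation field when one was used, else None.
    """
    from . import heterogeneity as het

    field_cache, bend_cache, h, pmap = cache
    if h is not None:
        dimage = apply_ctf(dimage, h)  # self-adjoint (even, real filter)
    ddens = pmap.MT @ dimage.ravel()
    dpts = field.backward(field_cache, ddens)
    if bend_cache is not None:
        return het.bend_backward(bend_cache, dpts)
    return None


def render_particle(
    field: ScalarField,
    grid: Grid,
    pose: Pose,
    jitter: JitterSpec | None = None,
    ctf: ImagingParams | np.ndarray | None = None,
    vf=None,
    pmap: ProjectionMap | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render the predicted image for one particle (no gradient caches)."""
    if pmap is None:
        pmap = build_projection_map(grid)
    image, _ = render_forward(
        field, grid, pmap, pose, ctf, jitter=jitter, rng=rng, vf=vf
    )
    return image
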