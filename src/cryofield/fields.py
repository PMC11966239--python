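"""Trainable scalar density fields f_theta: 3D coordinate -> density.

Three interchangeable parametrizations are provided:

``HashGridField``
    The flagship: a multi-resolution hashed feature grid (instant-NGP
    style) feeding a small ReLU MLP.  Each of L geometrically scaled
    levels stores learnable F-vectors in a table addressed either
    directly (when the level's lattice fits) or through a spatial hash;
    the 8 cell corners around a query are trilinearly blended.
``VoxelField``
    A dense trainable voxel array, trilinearly interpolated, zero
    outside the box.
``FourierFeatureField``
    Sinusoidal positional encodings (sin/cos octaves per axis) feeding
    the same MLP shape.

All fields expose ``forward``/``backward`` with explicit caches: the
package carries its own reverse-mode gradients (verified against finite
differences in the test suite), so every op that touches parameters
returns enough state to backpropagate exactly.

Physical coordinates (Angstrom, box centered at the origin) are mapped
to the canonical query domain [0, 1]^3 by one affine map owned by this
module: ``u = x / box_extent + 1/2``, clamped to the unit cube.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "HashGridConfig",
    "ScalarField",
    "HashGridField",
    "VoxelField",
    "FourierFeatureField",
    "AnalyticField",
    "MLP",
    "hash_encode",
    "render_volume",
    "load_field",
    "make_field",
]

# instant-NGP spatial-hash primes (first axis deliberately unmixed)
_HASH_PRIMES = (1, 2654435761, 805459861)


@dataclass
class HashGridConfig:
    """Hyperparameters of the multi-resolution hash encoder + decoder.

    ``log2_hashmap_size`` bounds each level's table; levels whose dense
    corner lattice (N+1)^3 fits inside the bound are indexed directly
    (collision-free), larger levels fall back to the spatial hash.
    ``finest_resolution`` should match the Nyquist limit of the data
    (n/2 cells across the box for an n-pixel image).
    """

    L: int = 8
    F: int = 2
    log2_hashmap_size: int = 14
    base_resolution: int = 16
    finest_resolution: int = 64
    mlp_hidden: int = 64
    mlp_layers: int = 2

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.finest_resolution < self.base_resolution:
            raise ValueError("finest_resolution must be >= base_resolution")

    @classmethod
    def for_box(cls, n_pixels: int, **kw) -> "HashGridConfig":
        """Config with the finest level Nyquist-matched to an n-pixel box.

        The base level is kept genuinely coarse (an octave spread of at
        least 8 below the finest level, floored at 4 cells per axis) so
        the hierarchy retains smooth large-scale levels even for small
        boxes; coarse levels carry the long-range gradients that drive
        pose-scale and deformation-scale displacements.
        """
        finest = max(n_pixels // 2, 8)
        base = kw.pop("base_resolution", None)
        if base is None:
            base = max(4, finest // 8)
        base = min(base, finest)
        return cls(base_resolution=base, finest_resolution=finest, **kw)

    def level_resolutions(self) -> np.ndarray:
        """Per-level cell counts, geometric from base to finest."""
        if self.L == 1:
            return np.array([self.base_resolution])
        g = np.exp(
            np.log(self.finest_resolution / self.base_resolution) / (self.L - 1)
        )
        res = np.floor(self.base_resolution * g ** np.arange(self.L)).astype(int)
        res[-1] = self.finest_resolution
        return res


class MLP:
    """Small fully connected ReLU network with a linear scalar head."""

    def __init__(
        self,
        in_dim: int,
        hidden: int,
        n_hidden: int,
        rng: np.random.Generator,
        out_dim: int = 1,
    ):
        self.shapes = [in_dim] + [hidden] * n_hidden + [out_dim]
        self.params: dict[str, np.ndarray] = {}
        for i, (d_in, d_out) in enumerate(zip(self.shapes[:-1], self.shapes[1:])):
            self.params[f"W{i}"] = rng.normal(0, np.sqrt(2.0 / d_in), (d_in, d_out))
            self.params[f"b{i}"] = np.zeros(d_out)
        self.n_layers = len(self.shapes) - 1
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    def forward(self, x: np.ndarray):
        acts = [x]
        h = x
        for i in range(self.n_layers):
            h = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            if i < self.n_layers - 1:
                h = np.maximum(h, 0.0)
            acts.append(h)
        return h, acts

    def backward(self, acts, dout: np.ndarray) -> np.ndarray:
        """Accumulate parameter grads; return gradient w.r.t. the input."""
        dh = dout
        for i in range(self.n_layers - 1, -1, -1):
            if i < self.n_layers - 1:
                dh = dh * (acts[i + 1] > 0)
            self.grads[f"W{i}"] += acts[i].T @ dh
            self.grads[f"b{i}"] += dh.sum(axis=0)
            dh = dh @ self.params[f"W{i}"].T
        return dh


class ScalarField:
    """Base class: trainable map from 3D physical coordinates to density."""

    tag = "abstract"

    def __init__(self, box_extent: float):
        self.box_extent = float(box_extent)
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    # -- canonical domain ------------------------------------------------
    def to_unit(self, points: np.ndarray):
        """Physical (A) -> [0,1]^3 with clamping; also return the clamp mask."""
        u = points / self.box_extent + 0.5
        inside = (u >= 0.0) & (u <= 1.0)
        return np.clip(u, 0.0, 1.0), inside

    # -- training surface ------------------------------------------------
    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def query(self, points: np.ndarray) -> np.ndarray:
        vals, _ = self.forward(points)
        return vals

    def forward(self, points: np.ndarray, need_dpoints: bool = False):
        raise NotImplementedError

    def backward(self, cache, dvals: np.ndarray):
        raise NotImplementedError

    # -- persistence -----------------------------------------------------
    def _config_dict(self) -> dict:
        return {}

    def save(self, path) -> None:
        meta = {"tag": self.tag, "box_extent": self.box_extent}
        meta.update(self._config_dict())
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.params)

    def load_params(self, archive) -> None:
        for k in self.params:
            self.params[k] = np.array(archive[k])
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


def _corner_offsets() -> np.ndarray:
    offs = np.array(
        [[(c >> 2) & 1, (c >> 1) & 1, c & 1] for c in range(8)], dtype=np.int64
    )
    return offs


_OFFS = _corner_offsets()


def _level_indices(corners: np.ndarray, resolution: int, table_size: int) -> np.ndarray:
    """Map (K, 8, 3) integer corner coordinates to table rows."""
    n_corner = resolution + 1
    if n_corner**3 <= table_size:
        return (
            corners[..., 0] * n_corner * n_corner
            + corners[..., 1] * n_corner
            + corners[..., 2]
        )
    h = (
        (corners[..., 0] * _HASH_PRIMES[0])
        ^ (corners[..., 1] * _HASH_PRIMES[1])
        ^ (corners[..., 2] * _HASH_PRIMES[2])
    )
    return h % table_size


def hash_encode(
    u: np.ndarray, config: HashGridConfig, tables: list[np.ndarray]
):
    """Multi-resolution hashed trilinear encoding of unit-cube points.

    Returns the (K, L*F) feature matrix and a cache for the backward
    pass.  Each level scales the point by its resolution, looks up the 8
    surrounding corner feature vectors (direct or hashed addressing) and
    blends them with trilinear weights.
    """
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite coordinates passed to hash_encode")
    K = u.shape[0]
    resolutions = config.level_resolutions()
    enc = np.empty((K, config.L * config.F))
    caches = []
    for lvl, (N, tab) in enumerate(zip(resolutions, tables)):
        s = u * N
        i0 = np.minimum(np.floor(s).astype(np.int64), N - 1)
        i0 = np.maximum(i0, 0)
        f = s - i0
        corners = i0[:, None, :] + _OFFS[None, :, :]
        idx = _level_indices(corners, int(N), tab.shape[0])
        w = _trilinear_weights(f)
        enc[:, lvl * config.F : (lvl + 1) * config.F] = np.einsum(
            "kc,kcf->kf", w, tab[idx]
        )
        caches.append((idx, f, int(N)))
    return enc, caches


def _trilinear_weights(f: np.ndarray) -> np.ndarray:
    """(K, 3) fractional positions -> (K, 8) corner weights."""
    one = 1.0 - f
    wx = np.where(_OFFS[None, :, 0] == 1, f[:, None, 0], one[:, None, 0])
    wy = np.where(_OFFS[None, :, 1] == 1, f[:, None, 1], one[:, None, 1])
    wz = np.where(_OFFS[None, :, 2] == 1, f[:, None, 2], one[:, None, 2])
    return wx * wy * wz


class HashGridField(ScalarField):
    """Multi-resolution hash-grid encoder with a ReLU MLP decoder."""

    tag = "hashgrid"

    def __init__(self, box_extent: float, config: HashGridConfig | None = None,
                 seed: int = 0):
        super().__init__(box_extent)
        self.config = config or HashGridConfig()
        rng = np.random.default_rng(seed)
        cap = 2 ** self.config.log2_hashmap_size
        self.table_names = []
        for lvl, N in enumerate(self.config.level_resolutions()):
            size = min((int(N) + 1) ** 3, cap)
            name = f"table{lvl}"
            self.params[name] = rng.uniform(-1e-4, 1e-4, (size, self.config.F))
            self.table_names.append(name)
        self.mlp = MLP(
            self.config.L * self.config.F,
            self.config.mlp_hidden,
            self.config.mlp_layers,
            rng,
        )
        self.params.update(self.mlp.params)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        # the MLP accumulates into its own grad dict; share storage
        for k in self.mlp.grads:
            self.mlp.grads[k] = self.grads[k]
        for k in self.mlp.params:
            self.mlp.params[k] = self.params[k]

    @property
    def tables(self) -> list[np.ndarray]:
        return [self.params[name] for name in self.table_names]

    def forward(self, points: np.ndarray, need_dpoints: bool = False):
        u, inside = self.to_unit(points)
        enc, enc_cache = hash_encode(u, self.config, self.tables)
        out, acts = self.mlp.forward(enc)
        return out[:, 0], (enc_cache, acts, inside, need_dpoints)

    def backward(self, cache, dvals: np.ndarray):
        enc_cache, acts, inside, need_dpoints = cache
        denc = self.mlp.backward(acts, dvals[:, None])
        F = self.config.F
        dpoints = (
            np.zeros((dvals.shape[0], 3)) if need_dpoints else None
        )
        for lvl, (idx, f, N) in enumerate(enc_cache):
            tab = self.params[self.table_names[lvl]]
            d_l = denc[:, lvl * F : (lvl + 1) * F]
            w = _trilinear_weights(f)
            np.add.at(
                self.grads[self.table_names[lvl]],
                idx,
                w[:, :, None] * d_l[:, None, :],
            )
            if need_dpoints:
                corner_dot = np.einsum("kcf,kf->kc", tab[idx], d_l)
                one = 1.0 - f
                sign = np.where(_OFFS[None, :, :] == 1, 1.0, -1.0)
                # dw/df_d = sign_d * product of the other two axis factors
                wx = np.where(_OFFS[None, :, 0] == 1, f[:, None, 0], one[:, None, 0])
                wy = np.where(_OFFS[None, :, 1] == 1, f[:, None, 1], one[:, None, 1])
                wz = np.where(_OFFS[None, :, 2] == 1, f[:, None, 2], one[:, None, 2])
                dpoints[:, 0] += N * np.sum(sign[:, :, 0] * wy * wz * corner_dot, axis=1)
                dpoints[:, 1] += N * np.sum(sign[:, :, 1] * wx * wz * corner_dot, axis=1)
                dpoints[:, 2] += N * np.sum(sign[:, :, 2] * wx * wy * corner_dot, axis=1)
        if need_dpoints:
            dpoints *= inside / self.box_extent
            return dpoints
        return None

    def _config_dict(self) -> dict:
        return {"config": asdict(self.config)}


class VoxelField(ScalarField):
    """Trainable dense voxel array, trilinearly interpolated, 0 outside."""

    tag = "voxel"

    def __init__(self, box_extent: float, n_voxels: int, seed: int = 0,
                 init: np.ndarray | None = None):
        super().__init__(box_extent)
        self.n_voxels = n_voxels
        if init is not None:
            if init.shape != (n_voxels,) * 3:
                raise ValueError("init volume shape mismatch")
            V = np.array(init, dtype=float)
        else:
            V = np.zeros((n_voxels,) * 3)
        self.params["V"] = V
        self.grads = {"V": np.zeros_like(V)}

    @property
    def spacing(self) -> float:
        return self.box_extent / self.n_voxels

    def forward(self, points: np.ndarray, need_dpoints: bool = False):
        n = self.n_voxels
        c = points / self.spacing + n / 2 - 0.5
        i0 = np.floor(c).astype(np.int64)
        f = c - i0
        corners = i0[:, None, :] + _OFFS[None, :, :]
        valid = np.all((corners >= 0) & (corners <= n - 1), axis=2)
        clipped = np.clip(corners, 0, n - 1)
        w = _trilinear_weights(f) * valid
        V = self.params["V"]
        vals = np.sum(w * V[clipped[..., 0], clipped[..., 1], clipped[..., 2]], axis=1)
        return vals, (clipped, valid, f, need_dpoints)

    def backward(self, cache, dvals: np.ndarray):
        clipped, valid, f, need_dpoints = cache
        w = _trilinear_weights(f) * valid
        flat = (
            clipped[..., 0] * self.n_voxels * self.n_voxels
            + clipped[..., 1] * self.n_voxels
            + clipped[..., 2]
        )
        np.add.at(self.grads["V"].ravel(), flat, w * dvals[:, None])
        if not need_dpoints:
            return None
        V = self.params["V"]
        cv = V[clipped[..., 0], clipped[..., 1], clipped[..., 2]] * valid
        one = 1.0 - f
        sign = np.where(_OFFS[None, :, :] == 1, 1.0, -1.0)
        wx = np.where(_OFFS[None, :, 0] == 1, f[:, None, 0], one[:, None, 0])
        wy = np.where(_OFFS[None, :, 1] == 1, f[:, None, 1], one[:, None, 1])
        wz = np.where(_OFFS[None, :, 2] == 1, f[:, None, 2], one[:, None, 2])
        dpoints = np.stack(
            [
                np.sum(sign[:, :, 0] * wy * wz * cv, axis=1),
                np.sum(sign[:, :, 1] * wx * wz * cv, axis=1),
                np.sum(sign[:, :, 2] * wx * wy * cv, axis=1),
            ],
            axis=1,
        )
        return dpoints * dvals[:, None] / self.spacing

    def _config_dict(self) -> dict:
        return {"n_voxels": self.n_voxels}


class FourierFeatureField(ScalarField):
    """Sinusoidal positional encoding (octaves of sin/cos) + MLP decoder."""

    tag = "frequency"

    def __init__(self, box_extent: float, n_octaves: int = 8,
                 mlp_hidden: int = 128, mlp_layers: int = 2, seed: int = 0):
        super().__init__(box_extent)
        self.n_octaves = n_octaves
        self.mlp_hidden = mlp_hidden
        self.mlp_layers = mlp_layers
        rng = np.random.default_rng(seed)
        self.freqs = (2.0 ** np.arange(n_octaves)) * np.pi
        self.mlp = MLP(3 * 2 * n_octaves, mlp_hidden, mlp_layers, rng)
        self.params = self.mlp.params
        self.grads = self.mlp.grads

    def _encode(self, u: np.ndarray) -> np.ndarray:
        phase = u[:, :, None] * self.freqs[None, None, :]  # (K, 3, O)
        K = u.shape[0]
        return np.concatenate(
            [np.sin(phase).reshape(K, -1), np.cos(phase).reshape(K, -1)], axis=1
        )

    def forward(self, points: np.ndarray, need_dpoints: bool = False):
        u, inside = self.to_unit(points)
        enc = self._encode(u)
        out, acts = self.mlp.forward(enc)
        return out[:, 0], (u, inside, acts, need_dpoints)

    def backward(self, cache, dvals: np.ndarray):
        u, inside, acts, need_dpoints = cache
        denc = self.mlp.backward(acts, dvals[:, None])
        if not need_dpoints:
            return None
        K = u.shape[0]
        O = self.n_octaves
        phase = u[:, :, None] * self.freqs[None, None, :]
        dsin = denc[:, : 3 * O].reshape(K, 3, O)
        dcos = denc[:, 3 * O :].reshape(K, 3, O)
        du = np.sum(
            (dsin * np.cos(phase) - dcos * np.sin(phase)) * self.freqs, axis=2
        )
        return du * inside / self.box_extent

    def _config_dict(self) -> dict:
        return {
            "n_octaves": self.n_octaves,
            "mlp_hidden": self.mlp_hidden,
            "mlp_layers": self.mlp_layers,
        }


class AnalyticField(ScalarField):
    """Read-only adapter wrapping a vectorized density function of (K,3) A."""

    tag = "analytic"

    def __init__(self, box_extent: float, fn):
        super().__init__(box_extent)
        self.fn = fn

    def forward(self, points: np.ndarray, need_dpoints: bool = False):
        if need_dpoints:
            raise ValueError("AnalyticField is not differentiable")
        return np.asarray(self.fn(points), dtype=float), None

    def backward(self, cache, dvals):  # pragma: no cover - contract only
        raise ValueError("AnalyticField has no trainable parameters")


def render_volume(field: ScalarField, n: int, pixel_size: float,
                  chunk: int = 65536) -> np.ndarray:
    """Sample a field on the standard n^3 voxel-center lattice.

    The result is indexed (x, y, z) and can be written as MRC via
    :func:`cryofield.io.write_mrc`.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    ax = (np.arange(n) - n / 2 + 0.5) * pixel_size
    A, B, C = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([A.ravel(), B.ravel(), C.ravel()], axis=1)
    out = np.empty(pts.shape[0])
    for start in range(0, pts.shape[0], chunk):
        out[start : start + chunk] = field.query(pts[start : start + chunk])
    return out.reshape(n, n, n)


def make_field(tag: str, box_extent: float, n_pixels: int, seed: int = 0,
               hash_config: HashGridConfig | None = None) -> ScalarField:
    """Factory keyed by parametrization tag (hashgrid | voxel | frequency)."""
    if tag == "hashgrid":
        cfg = hash_config or HashGridConfig.for_box(n_pixels)
        return HashGridField(box_extent, cfg, seed=seed)
    if tag == "voxel":
        return VoxelField(box_extent, n_pixels, seed=seed)
    if tag == "frequency":
        return FourierFeatureField(box_extent, seed=seed)
    raise ValueError(f"unknown field parametrization: {tag!r}")


def load_field(path) -> ScalarField:
    """Reload a field checkpoint written by ``ScalarField.save``."""
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        tag = meta["tag"]
        extent = meta["box_extent"]
        if tag == "hashgrid":
            field = HashGridField(extent, HashGridConfig(**meta["config"]))
        elif tag == "voxel":
            field = VoxelField(extent, meta["n_voxels"])
        elif tag == "frequency":
            field = FourierFeatureField(
                extent,
                n_octaves=meta["n_octaves"],
                mlp_hidden=meta["mlp_hidden"],
                mlp_layers=meta["mlp_layers"],
            )
        else:
            raise ValueError(f"unknown checkpoint tag {tag!r}")
        field.load_params(archive)
    if isinstance(field, HashGridField):
        for k in field.mlp.params:
            field.mlp.params[k] = field.params[k]
            field.mlp.grads[k] = field.grads[k]
    elif isinstance(field, FourierFeatureField):
        field.mlp.params = field.params
        field.mlp.grads = field.grads
    return field
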