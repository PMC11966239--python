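"""Per-image conformational heterogeneity by bending space.

Each particle image is mapped by a shared (amortized) network to a
coarse canonical displacement field of shape (3, n_F, n_F, n_F) on a
regular lattice spanning the box.  The field is trilinearly interpolated
at the particle's posed, jittered query points and *added* to them
before the scalar-density query — a reverse mapping: displacements are
looked up at the output coordinates rather than pushed from inputs.
Because the canonical field is pose independent and only its sampling
points are pose specific, the per-image field is SE(3) equivariant.

Smoothness comes from the coarseness of the lattice itself (nearby
points share interpolation corners); no explicit regularizer is used.
State assignment clusters the cosine-similarity matrix of the flattened
per-image fields.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import SpectralClustering

from .fields import MLP, _OFFS, _trilinear_weights

__all__ = [
    "VectorFieldModel",
    "bend",
    "bend_forward",
    "bend_backward",
    "cosine_similarity_matrix",
    "cluster_states",
    "match_labels",
]


class VectorFieldModel:
    """Amortized image -> canonical deformation field network.

    A fixed average-pooling stage reduces the image to ``pooled x pooled``
    pixels; a small ReLU MLP maps it to a latent vector and a linear,
    zero-initialized head reshapes to (3, n_F, n_F, n_F).  The zero head
    makes the initial deformation exactly zero, so training starts at
    the homogeneous model.

    The scalar field and an image-independent deformation share a gauge
    freedom: a constant warp can be traded between the two with no effect
    on the rendered images, so the shared component of the predicted
    fields is arbitrary and can drift during training.  Two measures deal
    with it:

    * the head has no bias term (a pure image-independent channel) and the
      training loop applies decoupled weight decay to the encoder, the
      restoring force that migrates shared deformation into the field;
    * an exponential moving average of the fields predicted during
      training (``center_momentum``) is kept as a consensus-deformation
      buffer; ``predict_field(..., center=True)`` subtracts it, yielding
      the per-image *deviation* from the mean conformation.  State
      analysis uses centered fields so the cosine similarity contrasts
      conformations rather than the residual shared warp.

    The rendering path always uses the raw field (it is what the scalar
    field was trained against).
    """

    def __init__(
        self,
        n_pixels: int,
        n_field: int = 8,
        pooled: int = 16,
        hidden: int = 128,
        seed: int = 0,
        center_momentum: float = 0.99,
    ):
        if n_pixels % pooled != 0:
            # fall back to the largest divisor <= requested pooling
            divs = [d for d in range(1, n_pixels + 1) if n_pixels % d == 0]
            pooled = max(d for d in divs if d <= pooled)
        self.n_pixels = n_pixels
        self.n_field = n_field
        self.pooled = pooled
        self.hidden = hidden
        self.center_momentum = center_momentum
        rng = np.random.default_rng(seed)
        out_dim = 3 * n_field**3
        self.mlp = MLP(pooled * pooled, hidden, 1, rng, out_dim=out_dim)
        # zero-init the head: identity deformation at initialization
        last = self.mlp.n_layers - 1
        self._head_bias = f"b{last}"
        self.mlp.params[f"W{last}"][...] = 0.0
        self.mlp.params[self._head_bias][...] = 0.0
        # the head bias is excluded from the trainable set: it could only
        # ever represent an image-independent deformation
        self.params = {
            f"enc_{k}": v for k, v in self.mlp.params.items()
            if k != self._head_bias
        }
        self.grads = {
            f"enc_{k}": v for k, v in self.mlp.grads.items()
            if k != self._head_bias
        }
        self.field_mean = np.zeros((3, n_field, n_field, n_field))

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    def _pool(self, image: np.ndarray) -> np.ndarray:
        # standardize per image so the encoder sees shape, not the
        # arbitrary contrast scale the loss is invariant to
        sd = image.std()
        if sd > 0:
            image = (image - image.mean()) / sd
        k = self.n_pixels // self.pooled
        return image.reshape(self.pooled, k, self.pooled, k).mean(axis=(1, 3))

    def forward(self, image: np.ndarray, update_stats: bool = False):
        if image.shape != (self.n_pixels, self.n_pixels):
            raise ValueError(
                f"image shape {image.shape} does not match box size "
                f"{self.n_pixels}"
            )
        x = self._pool(image).reshape(1, -1)
        out, acts = self.mlp.forward(x)
        nf = self.n_field
        raw = out.reshape(3, nf, nf, nf)
        if update_stats:
            m = self.center_momentum
            self.field_mean = m * self.field_mean + (1 - m) * raw
        return raw, acts

    def backward(self, acts, dfield: np.ndarray) -> None:
        self.mlp.backward(acts, dfield.reshape(1, -1))

    def predict_field(self, image: np.ndarray, center: bool = False) -> np.ndarray:
        """Deterministic canonical field for one image (no caches).

        ``center=True`` subtracts the consensus-deformation buffer
        accumulated during training; use it for state analysis.
        """
        field, _ = self.forward(image)
        if center:
            return field - self.field_mean
        return field

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        import json

        meta = {
            "n_pixels": self.n_pixels,
            "n_field": self.n_field,
            "pooled": self.pooled,
            "hidden": self.hidden,
            "center_momentum": self.center_momentum,
        }
        arrays = {f"enc_{k}": v for k, v in self.mlp.params.items()}
        arrays["field_mean"] = self.field_mean
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "VectorFieldModel":
        import json

        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            model = cls(**{k: meta[k] for k in
                           ("n_pixels", "n_field", "pooled", "hidden",
                            "center_momentum")})
            for k in model.mlp.params:
                model.mlp.params[k][...] = archive[f"enc_{k}"]
            model.field_mean = np.array(archive["field_mean"])
        return model


def predict_field(model: VectorFieldModel, image: np.ndarray) -> np.ndarray:
    return model.predict_field(image)


def _field_fractional(points: np.ndarray, n_field: int, box_extent: float):
    """Continuous lattice coordinates of physical points on the field grid.

    The canonical lattice has n_F nodes per axis spanning the full box
    [-E/2, E/2]; out-of-box points clamp to the boundary cells.
    """
    span = box_extent
    c = (points / span + 0.5) * (n_field - 1)
    c = np.clip(c, 0.0, n_field - 1)
    i0 = np.minimum(np.floor(c).astype(np.int64), n_field - 2)
    i0 = np.maximum(i0, 0)
    return i0, c - i0


def bend_forward(points: np.ndarray, field: np.ndarray, box_extent: float):
    """Interpolate the canonical field at the points and add it.

    Returns the bent points and a cache for backpropagation to the field
    values (reverse-mapping: the displacement is queried at the output
    grid coordinates).
    """
    if field.ndim != 4 or field.shape[0] != 3:
        raise ValueError("vector field must have shape (3, n_F, n_F, n_F)")
    nf = field.shape[1]
    i0, f = _field_fractional(points, nf, box_extent)
    corners = i0[:, None, :] + _OFFS[None, :, :]
    w = _trilinear_weights(f)
    disp = np.einsum(
        "kc,dkc->kd",
        w,
        field[:, corners[..., 0], corners[..., 1], corners[..., 2]],
    )
    cache = (corners, w, field.shape)
    return points + disp, cache


def bend_backward(cache, dbent: np.ndarray) -> np.ndarray:
    """Gradient of the bent coordinates w.r.t. the canonical field values."""
    corners, w, shape = cache
    dfield = np.zeros(shape)
    nf = shape[1]
    flat = (
        corners[..., 0] * nf * nf + corners[..., 1] * nf + corners[..., 2]
    )
    contrib = w[:, :, None] * dbent[:, None, :]  # (K, 8, 3)
    for d in range(3):
        np.add.at(dfield[d].ravel(), flat, contrib[..., d])
    return dfield


def bend(points: np.ndarray, field: np.ndarray, box_extent: float) -> np.ndarray:
    """Bent points only (no cache): points + interpolated displacement."""
    bent, _ = bend_forward(points, field, box_extent)
    return bent


def cosine_similarity_matrix(fields) -> np.ndarray:
    """Pairwise cosine similarity of flattened per-image fields."""
    X = np.stack([np.asarray(f).ravel() for f in fields])
    if X.shape[0] < 2:
        raise ValueError("need at least two fields")
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError("cosine similarity undefined for a zero-norm field")
    U = X / norms[:, None]
    S = U @ U.T
    np.fill_diagonal(S, 1.0)
    return S


def cluster_states(similarity: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Spectral clustering of the similarity matrix into k state labels."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > similarity.shape[0]:
        raise ValueError("k exceeds the number of images")
    affinity = (similarity + 1.0) / 2.0  # map [-1, 1] -> [0, 1]
    model = SpectralClustering(
        n_clusters=k, affinity="precomputed", random_state=seed,
        assign_labels="discretize",
    )
    return model.fit_predict(affinity)


def export_fields(fields, path) -> None:
    """Write per-image canonical fields to one array archive (.npz)."""
    stack = np.stack([np.asarray(f) for f in fields])
    np.savez_compressed(path, fields=stack)


def state_average_slices(fields, labels, box_extent: float,
                         thickness: int = 8):
    """Per-state mean in-plane deformation on the central slab.

    Averages each state's canonical fields, then averages the middle
    ``thickness`` z-layers into one 2D slice.  Returns a DataFrame per
    state with columns x, y (A), dx, dy (A) and magnitude — quiver-ready.
    """
    import pandas as pd

    stack = np.stack([np.asarray(f) for f in fields])
    labels = np.asarray(labels)
    nf = stack.shape[2]
    z0 = max((nf - thickness) // 2, 0)
    z1 = min(z0 + thickness, nf)
    nodes = np.linspace(-box_extent / 2, box_extent / 2, nf)
    out = {}
    for state in np.unique(labels):
        mean = stack[labels == state].mean(axis=0)
        slab = mean[:, :, :, z0:z1].mean(axis=3)  # (3, nf, nf)
        X, Y = np.meshgrid(nodes, nodes, indexing="ij")
        out[int(state)] = pd.DataFrame(
            {
                "x": X.ravel(),
                "y": Y.ravel(),
                "dx": slab[0].ravel(),
                "dy": slab[1].ravel(),
                "magnitude": np.sqrt(slab[0] ** 2 + slab[1] ** 2).ravel(),
            }
        )
    return out


def match_labels(true: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Permute predicted labels to best match ground truth (greedy Hungarian).

    Resolves the label-permutation ambiguity of clustering before
    computing classification metrics.
    """
    from scipy.optimize import linear_sum_assignment

    true = np.asarray(true)
    pred = np.asarray(pred)
    k = int(max(true.max(), pred.max())) + 1
    cost = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            cost[i, j] = -np.sum((pred == i) & (true == j))
    rows, cols = linear_sum_assignment(cost)
    mapping = dict(zip(rows, cols))
    return np.array([mapping[p] for p in pred])
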