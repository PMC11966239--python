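"""Optimization loop: fit a scalar field (and optionally a deformation
encoder) to a particle stack with known poses and CTFs.

Each gradient step renders the predicted image for every particle in
the minibatch through the differentiable forward model (fresh jitter
draws per forward pass), sums the per-particle losses, backpropagates
to the field parameters (and encoder parameters when heterogeneity is
on) and applies one AdamW update.  Hash tables get a larger learning
rate than the MLPs, following common practice for hashed feature grids.
Runs are reproducible from a single seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .fields import HashGridConfig, ScalarField, make_field
from .forward_model import (
    Particle,
    ProjectionMap,
    build_projection_map,
    ctf_array,
    render_backward,
    render_forward,
)
from .geometry import Grid, JitterSpec, MaskVolume, build_grid, subset_by_mask
from .heterogeneity import VectorFieldModel
from .losses import LossSpec, make_loss
from .optim import AdamW
from .validation import fsc

__all__ = ["RunConfig", "TrainResult", "train", "run_half_maps"]


@dataclass
class RunConfig:
    """Hyperparameters of one training run."""

    field_kind: str = "hashgrid"
    hash_config: HashGridConfig | None = None
    n_z: int = 64  # depth samples |G_z|
    jitter: float = 0.0  # J in A
    loss: LossSpec = dc_field(default_factory=LossSpec)
    lr_tables: float = 1e-2
    lr_mlp: float = 1e-3
    lr_encoder: float = 5e-3
    weight_decay: float = 0.0
    # decoupled decay on the deformation encoder: the restoring force that
    # migrates any image-independent deformation into the scalar field
    # (strong enough to pin the gauge, weak enough not to crush the
    # image-conditional signal)
    weight_decay_encoder: float = 0.1
    # cosine learning-rate decay to this fraction of the base rates by the
    # final step; 1.0 keeps the rates constant
    lr_final_fraction: float = 1.0
    # streaming updates (one optimizer step per particle) by default: in
    # the one-epoch regime a few hundred batched steps cannot converge
    batch_size: int = 1
    epochs: int = 1
    seed: int = 0
    val_fraction: float = 0.05
    val_every: int = 100
    heterogeneous: bool = False
    n_field: int = 8
    encoder_hidden: int = 128

    def __post_init__(self) -> None:
        if self.n_z < 1:
            raise ValueError("n_z must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 <= self.val_fraction < 1:
            raise ValueError("val_fraction must be in [0, 1)")


@dataclass
class TrainResult:
    field: ScalarField
    grid: Grid
    pmap: ProjectionMap
    log: pd.DataFrame
    vf_model: VectorFieldModel | None = None
    checkpoints: list = dc_field(default_factory=list)


def _lr_map(params: dict, config: RunConfig) -> dict:
    lrs = {}
    for name in params:
        if name.startswith("table"):
            lrs[name] = config.lr_tables
        elif name.startswith("enc_"):
            lrs[name] = config.lr_encoder
        else:
            lrs[name] = config.lr_mlp
    return lrs


def train(
    particles: list[Particle],
    n_pixels: int,
    pixel_size: float,
    config: RunConfig,
    mask: MaskVolume | None = None,
    field: ScalarField | None = None,
    vf_model: VectorFieldModel | None = None,
    checkpoint_steps: tuple[int, ...] = (),
    on_checkpoint=None,
    log_path=None,
) -> TrainResult:
    """Fit a field to a particle stack; returns the field and loss logs.

    ``checkpoint_steps`` requests snapshots: after those optimizer steps
    ``on_checkpoint(field, step)`` is called and its return value is
    collected in ``TrainResult.checkpoints`` (used e.g. to track masked
    volume correlation over training).
    """
    rng = np.random.default_rng(config.seed)
    grid = build_grid(n_pixels, pixel_size, config.n_z)
    if mask is not None:
        grid = subset_by_mask(grid, mask)
    # a masked grid already carries only surviving points, so the
    # projection map is built with the matching columns dropped
    pmap = build_projection_map(grid)

    if field is None:
        field = make_field(
            config.field_kind,
            n_pixels * pixel_size,
            n_pixels,
            seed=config.seed,
            hash_config=config.hash_config,
        )
    all_params = dict(field.params)
    all_grads = dict(field.grads)
    if not config.heterogeneous:
        vf_model = None
    elif vf_model is None:
        vf_model = VectorFieldModel(
            n_pixels,
            n_field=config.n_field,
            hidden=config.encoder_hidden,
            seed=config.seed + 1,
        )
    if vf_model is not None:
        all_params.update(vf_model.params)
        all_grads.update(vf_model.grads)

    wd = {
        k: (config.weight_decay_encoder if k.startswith("enc_")
            else config.weight_decay)
        for k in all_params
    }
    opt = AdamW(all_params, lr=_lr_map(all_params, config), weight_decay=wd)
    loss_fn = make_loss(config.loss)
    jitter = JitterSpec(J=config.jitter, rng_seed=config.seed)

    n_total = len(particles)
    order = rng.permutation(n_total)
    n_val = int(round(config.val_fraction * n_total))
    val_idx = order[:n_val]
    train_idx = order[n_val:]
    if train_idx.size == 0:
        raise ValueError("no training particles left after validation split")

    ctfs = {i: ctf_array(n_pixels, particles[i].ctf) for i in range(n_total)}

    def _particle_pass(i: int, with_grad: bool):
        p = particles[i]
        vf = None
        acts = None
        if vf_model is not None:
            vf, acts = vf_model.forward(p.image, update_stats=with_grad)
        img, cache = render_forward(
            field, grid, pmap, p.pose, ctfs[i],
            jitter=jitter if with_grad else None,
            rng=rng, vf=vf,
        )
        l, dimg = loss_fn(p.image, img)
        if with_grad:
            dvf = render_backward(field, cache, dimg)
            if vf_model is not None:
                vf_model.backward(acts, dvf)
        return l

    records = []
    checkpoints = []
    step = 0
    steps_per_epoch = int(np.ceil(train_idx.size / config.batch_size))
    total_steps = config.epochs * steps_per_epoch
    t0 = time.perf_counter()
    for _ in range(config.epochs):
        epoch_order = rng.permutation(train_idx)
        for start in range(0, epoch_order.size, config.batch_size):
            batch = epoch_order[start : start + config.batch_size]
            if config.lr_final_fraction != 1.0:
                frac = config.lr_final_fraction
                cos = 0.5 * (1 + np.cos(np.pi * step / max(total_steps - 1, 1)))
                opt.set_lr_scale(frac + (1 - frac) * cos)
            field.zero_grad()
            if vf_model is not None:
                vf_model.zero_grad()
            batch_loss = sum(_particle_pass(i, True) for i in batch)
            opt.step(all_grads)
            step += 1
            val_loss = np.nan
            if val_idx.size and (step % config.val_every == 0):
                val_loss = float(
                    np.mean([_particle_pass(i, False) for i in val_idx])
                )
            records.append(
                {
                    "step": step,
                    "train_loss": float(batch_loss),
                    "val_loss": val_loss,
                    "wall_time_s": time.perf_counter() - t0,
                }
            )
            if step in checkpoint_steps and on_checkpoint is not None:
                checkpoints.append(on_checkpoint(field, step))

    log = pd.DataFrame(records)
    if log_path is not None:
        log.to_csv(log_path, index=False)
    return TrainResult(
        field=field, grid=grid, pmap=pmap, log=log, vf_model=vf_model,
        checkpoints=checkpoints,
    )


def run_half_maps(
    particles: list[Particle],
    n_pixels: int,
    pixel_size: float,
    config: RunConfig,
    split: tuple[np.ndarray, np.ndarray] | None = None,
    render_n: int | None = None,
    reference: np.ndarray | None = None,
):
    """Train two independent fields on disjoint particle halves.

    Returns a dict with both TrainResults, the half-map FSC curve, and
    (when a reference volume is supplied) each half's FSC to it.
    """
    from .fields import render_volume

    n_total = len(particles)
    if split is None:
        rng = np.random.default_rng(config.seed)
        order = rng.permutation(n_total)
        split = (order[: n_total // 2], order[n_total // 2 :])
    a, b = (np.asarray(s) for s in split)
    if np.intersect1d(a, b).size:
        raise ValueError("half-map split must be disjoint")
    if a.size + b.size != n_total:
        raise ValueError("half-map split must cover all particles")

    cfg_b = RunConfig(**{**config.__dict__, "seed": config.seed + 1})
    res_a = train([particles[i] for i in a], n_pixels, pixel_size, config)
    res_b = train([particles[i] for i in b], n_pixels, pixel_size, cfg_b)
    n = render_n or n_pixels
    vol_a = render_volume(res_a.field, n, pixel_size)
    vol_b = render_volume(res_b.field, n, pixel_size)
    out = {
        "half_a": res_a,
        "half_b": res_b,
        "split_sizes": (int(a.size), int(b.size)),
        "fsc_half_maps": fsc(vol_a, vol_b, pixel_size),
    }
    if reference is not None:
        out["fsc_a_to_reference"] = fsc(vol_a, reference, pixel_size)
        out["fsc_b_to_reference"] = fsc(vol_b, reference, pixel_size)
    return out
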