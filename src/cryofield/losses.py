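"""Gaussian-white-noise objectives: MSE, scale-invariant CC, and BioEM.

All three losses assume per-pixel i.i.d. Gaussian noise.  MSE is the
plain negative log-likelihood at known sigma.  The CC loss standardizes
both images first (zero mean, unit std per image) and is therefore
invariant to global multiplicative and additive rescaling of either
image; sigma only scales it by a constant.  The BioEM loss analytically
marginalizes a global scale N and offset mu of the prediction under
Gaussian priors (scale centered at 1, offset at 0) and removes the noise
level by a saddle point over sigma; the Gaussian prior keeps the loss
finite and prevents the degenerate minimum at ||yhat|| -> 0 that the
original flat-prior marginalization exhibits under end-to-end training.

Each loss also has a ``*_grad`` companion returning (loss, dloss/dyhat);
the gradients are exact (BioEM uses the envelope theorem at the sigma
saddle point) and are finite-difference-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "LossSpec",
    "loss_mse",
    "loss_mse_grad",
    "loss_cc",
    "loss_cc_grad",
    "loss_bioem",
    "loss_bioem_grad",
    "BioEMPrior",
    "make_loss",
]

_SIGMA_FLOOR = 1e-6


def _check_shapes(y: np.ndarray, yhat: np.ndarray) -> None:
    if y.shape != yhat.shape:
        raise ValueError(f"image shape mismatch: {y.shape} vs {yhat.shape}")


def loss_mse(y: np.ndarray, yhat: np.ndarray, sigma: float = 1.0) -> float:
    """Negative Gaussian log-likelihood up to constants: sum (y-yhat)^2 / 2 sigma^2."""
    _check_shapes(y, yhat)
    return float(np.sum((y - yhat) ** 2) / (2.0 * sigma * sigma))


def loss_mse_grad(y: np.ndarray, yhat: np.ndarray, sigma: float = 1.0):
    _check_shapes(y, yhat)
    d = (yhat - y) / (sigma * sigma)
    return float(np.sum((y - yhat) ** 2) / (2.0 * sigma * sigma)), d


def _standardize(x: np.ndarray):
    mu = x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant image in the CC loss")
    return (x - mu) / sd, sd


def loss_cc(y: np.ndarray, yhat: np.ndarray, sigma: float = 1.0) -> float:
    """Squared distance between the standardized images, / 2 sigma^2.

    Equals (P / sigma^2) * (1 - r) for Pearson r over P pixels: zero iff
    the images are perfectly correlated, invariant to a*y+b and c*yhat+d
    for a, c > 0.
    """
    _check_shapes(y, yhat)
    wy, _ = _standardize(y)
    wc, _ = _standardize(yhat)
    return float(np.sum((wy - wc) ** 2) / (2.0 * sigma * sigma))


def loss_cc_grad(y: np.ndarray, yhat: np.ndarray, sigma: float = 1.0):
    _check_shapes(y, yhat)
    wy, _ = _standardize(y)
    wc, sd = _standardize(yhat)
    P = y.size
    val = float(np.sum((wy - wc) ** 2) / (2.0 * sigma * sigma))
    dwc = (wc - wy) / (sigma * sigma)
    # Jacobian of standardization: (I - 11^T/P - wc wc^T/P) / sd
    d = (dwc - dwc.mean() - wc * np.sum(dwc * wc) / P) / sd
    return val, d


@dataclass
class BioEMPrior:
    """Gaussian prior over the global scale and offset of the prediction."""

    scale_mean: float = 1.0
    offset_mean: float = 0.0
    std: float = 10.0

    def __post_init__(self) -> None:
        if self.std <= 0:
            raise ValueError("BioEM prior std must be > 0")


def _bioem_neglog(sigma2: float, stats, prior: BioEMPrior):
    """-log marginal likelihood at fixed sigma^2, plus posterior quantities."""
    P, Sy, Sc, Syy, Scc, Syc = stats
    s2 = prior.std**2
    A = np.array(
        [
            [Scc / sigma2 + 1.0 / s2, Sc / sigma2],
            [Sc / sigma2, P / sigma2 + 1.0 / s2],
        ]
    )
    b = np.array(
        [
            Syc / sigma2 + prior.scale_mean / s2,
            Sy / sigma2 + prior.offset_mean / s2,
        ]
    )
    const = Syy / (2.0 * sigma2) + (
        prior.scale_mean**2 + prior.offset_mean**2
    ) / (2.0 * s2)
    iA = np.linalg.inv(A)
    xhat = iA @ b
    sign, logdet = np.linalg.slogdet(A)
    if sign <= 0:
        raise FloatingPointError("BioEM precision matrix not positive definite")
    nll = (
        0.5 * P * np.log(2.0 * np.pi * sigma2)
        - np.log(2.0 * np.pi)
        + np.log(2.0 * np.pi * s2)
        + 0.5 * logdet
        - 0.5 * b @ xhat
        + const
    )
    return nll, iA, xhat


def _bioem_stats(y: np.ndarray, yhat: np.ndarray):
    stats = (
        y.size,
        float(np.sum(y)),
        float(np.sum(yhat)),
        float(np.sum(y * y)),
        float(np.sum(yhat * yhat)),
        float(np.sum(y * yhat)),
    )
    if not all(np.isfinite(stats)):
        raise ValueError("non-finite sufficient statistics in the BioEM loss")
    return stats


def _bioem_saddle(stats, prior: BioEMPrior):
    """Minimize the -log marginal over log sigma^2 (bounded 1D search)."""
    scale = max(stats[3] / stats[0], _SIGMA_FLOOR)  # mean y^2 sets the scale

    def obj(t):
        return _bioem_neglog(np.exp(t), stats, prior)[0]

    res = minimize_scalar(
        obj,
        bounds=(np.log(scale * 1e-12 + _SIGMA_FLOOR**2), np.log(scale * 1e4)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(np.exp(res.x))


def loss_bioem(
    y: np.ndarray, yhat: np.ndarray, prior: BioEMPrior | None = None
) -> float:
    """Scale/offset-marginalized negative log-likelihood (sigma saddle point).

    Depends on the images only through P, sum y, sum yhat, sum y^2,
    sum yhat^2 and sum y.yhat.
    """
    _check_shapes(y, yhat)
    prior = prior or BioEMPrior()
    stats = _bioem_stats(y, yhat)
    sigma2 = _bioem_saddle(stats, prior)
    return float(_bioem_neglog(sigma2, stats, prior)[0])


def loss_bioem_grad(
    y: np.ndarray, yhat: np.ndarray, prior: BioEMPrior | None = None
):
    """BioEM loss and its exact gradient w.r.t. yhat.

    At the sigma saddle point the total derivative reduces to the partial
    at fixed sigma (envelope theorem); that partial is analytic in the
    sufficient statistics.
    """
    _check_shapes(y, yhat)
    prior = prior or BioEMPrior()
    stats = _bioem_stats(y, yhat)
    sigma2 = _bioem_saddle(stats, prior)
    nll, iA, xhat = _bioem_neglog(sigma2, stats, prior)
    # dL/dyhat_j = (1/sigma2) [ yhat_j (iA00 + xhat0^2) + iA01 + xhat0*xhat1
    #                           - xhat0 * y_j ]
    d = (
        yhat * (iA[0, 0] + xhat[0] ** 2)
        + iA[0, 1]
        + xhat[0] * xhat[1]
        - xhat[0] * y
    ) / sigma2
    return float(nll), d


@dataclass
class LossSpec:
    """Configured objective: kind in {mse, cc, bioem} plus hyperparameters."""

    kind: str = "cc"
    sigma: float = 3.0
    bioem_prior: BioEMPrior = dc_field(default_factory=BioEMPrior)

    def __post_init__(self) -> None:
        if self.kind not in ("mse", "cc", "bioem"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.kind in ("mse", "cc") and self.sigma <= 0:
            raise ValueError("sigma must be > 0 for mse/cc losses")


def make_loss(spec: LossSpec):
    """Return a callable (y, yhat) -> (loss, dloss/dyhat)."""
    if spec.kind == "mse":
        return lambda y, yhat: loss_mse_grad(y, yhat, spec.sigma)
    if spec.kind == "cc":
        return lambda y, yhat: loss_cc_grad(y, yhat, spec.sigma)
    return lambda y, yhat: loss_bioem_grad(y, yhat, spec.bioem_prior)
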